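"""Candidate triage: rule-of-five check and activity prediction.

Applies Lipinski violation counting to the bundled candidate property
profiles, then predicts pIC50 for each candidate with the published
four-descriptor equation, writing the ranked report.
"""

from pathlib import Path

from coxqsar import load_candidate_table, load_reference_models
from coxqsar.pipeline import PipelineConfig, run_screen

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tetra = load_reference_models()["tetra"]
    result = run_screen(
        PipelineConfig(output_dir=str(RESULTS)),
        model=tetra,
        candidates=load_candidate_table(),
    )
    print("ranked candidates (tetra equation):")
    for _, row in result.report.iterrows():
        print(
            f"  {row['id']:>10}: predicted pIC50 {row['predicted_pic50']:.4f} "
            f"({row['lipinski_violations']} Lipinski violation(s), role {row['role']})"
        )
    if result.exclusions:
        print(f"excluded: {result.exclusions}")
    print(f"wrote {RESULTS / 'candidates_ranked.csv'}")


if __name__ == "__main__":
    main()
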