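"""Correlation screening and exhaustive model enumeration.

Loads the bundled 20-compound training set, reports each descriptor's
Pearson correlation with pIC50, applies the |rho| >= 0.4 selection, fits
all 15 descriptor-subset OLS models, and writes the ranked leaderboard.
"""

from pathlib import Path

from coxqsar import (
    build_correlation_report,
    build_leaderboard,
    load_training_table,
    select_descriptors,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    training = load_training_table()
    report = build_correlation_report(training, cutoff=0.4)
    print("descriptor correlations with pIC50:")
    for name, rho in zip(report.descriptor_names, report.vs_activity):
        print(f"  {name:>5}: {rho:+.4f}")
    selected = select_descriptors(report)
    print(f"selected at |rho| >= {report.cutoff}: {'+'.join(selected)}")

    leaderboard = build_leaderboard(training, selected, max_p=4)
    frame = leaderboard.to_frame()
    RESULTS.mkdir(exist_ok=True)
    report.to_frame().to_csv(RESULTS / "correlation_report.csv", float_format="%.4f")
    frame.to_csv(RESULTS / "leaderboard.csv", index=False, float_format="%.4f")

    best = leaderboard.best
    print(f"\n{len(leaderboard.models)} models fitted; best by R2: {best.model_id}")
    print(
        f"  R={best.stats['R']:.4f} R2={best.stats['R2']:.4f} "
        f"adjR2={best.stats['R2_adj']:.4f} SEE={best.stats['SEE']:.4f} "
        f"F={best.stats['F']:.4f}"
    )
    print(f"wrote {RESULTS / 'leaderboard.csv'}")


if __name__ == "__main__":
    main()
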