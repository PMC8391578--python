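"""Epoch-length sweep: 2 s / 5 s / 10 s windows at 50% overlap.

Re-runs the comparison for the three epoch settings the pipeline supports
out of the box ((duration, stride) = (2,1), (5,2.5), (10,5)) on a small
two-class cohort, to show how the epoch grid trades row count against
per-epoch stability. Output: results/sweep/.
"""
import sys
from pathlib import Path

from eegcv import CohortSpec, ExperimentConfig, epoch_sweep

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    spec = CohortSpec(n_per_class={"AD": 3, "CN": 3}, duration_s=120.0, seed=seed)
    cfg = ExperimentConfig(cohort=spec, classifiers=("decision_tree", "random_forest"),
                           seed=seed)
    reports = epoch_sweep(cfg, [2.0, 5.0, 10.0], [1.0, 2.5, 5.0])
    for (dur, stride), report in sorted(reports.items()):
        report.save(RESULTS / "sweep" / f"epoch{dur:g}s_stride{stride:g}s")
        n = sum(f.counts.total for f in next(iter(report.summaries.values())).folds)
        t = report.table
        print(f"epoch {dur:g} s / stride {stride:g} s: {n} epochs; "
              f"kfold acc {t['kfold_accuracy'].mean():.3f}, "
              f"lopo acc {t['lopo_accuracy'].mean():.3f}")
    print(f"reports saved under {RESULTS / 'sweep'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
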