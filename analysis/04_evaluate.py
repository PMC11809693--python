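#!/usr/bin/env python
"""Full evaluation: gold standard, session QC, pooled and per-session
sensitivity/specificity, and minute-level rate agreement.

Runs the pipeline on results/cohort/ and writes the report bundle
(offsets, evaluable dataset, QC flowchart, the three result tables and
metrics.json, plus the two agreement figures) to results/evaluation/.
"""

import json
from pathlib import Path

from coughval.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig(
        manifest=str(ROOT / "cohort" / "manifest.yaml"),
        out_dir=str(ROOT / "evaluation"),
        seed=20210901,
        make_plots=True,
    )
    report = run_pipeline(config)

    flow = report["flowchart"]
    print(f"Sessions: {flow['total_sessions']} recorded, "
          f"{flow['excluded']['sync_failure']} unsynchronizable, "
          f"{flow['excluded']['too_few_coughs']} below the 10-unanimous-cough "
          f"quality bar, {flow['included_sessions']} evaluated.")
    for dev, p in sorted(report["pooled"].items()):
        se, sp = 100 * p["sensitivity"], 100 * p["specificity"]
        se_ci = [100 * v for v in p["sensitivity_ci"]]
        sp_ci = [100 * v for v in p["specificity_ci"]]
        print(f"{dev}: sensitivity {se:.1f}% (95% CI {se_ci[0]:.1f}-{se_ci[1]:.1f}), "
              f"specificity {sp:.1f}% (95% CI {sp_ci[0]:.1f}-{sp_ci[1]:.1f}) "
              f"[TP {p['tp']} FP {p['fp']} FN {p['fn']} TN {p['tn']}]")
    for name, a in sorted(report["agreement"].items()):
        ba = a["bland_altman"]
        print(f"rate agreement {name}: r = {a['pearson_r']:.3f}, "
              f"fit = {a['intercept']:.2f} + {a['slope']:.2f} x gold, "
              f"Bland-Altman bias {ba['mean_pct_error']:.1f}% "
              f"(LoA {ba['loa_lower']:.1f} to {ba['loa_upper']:.1f}%)")
    print(f"Report bundle in {ROOT / 'evaluation'}")


if __name__ == "__main__":
    main()
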