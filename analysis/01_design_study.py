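#!/usr/bin/env python
"""Study design: how many solicited sounds are needed, and what a session
script looks like.

Writes the five canonical script versions and the sample-size table to
results/design/.
"""

from pathlib import Path

import pandas as pd

from coughval.study_design import (
    SampleSizeSpec,
    buderer_sample_size,
    canonical_script,
    write_script,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "design"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    spec = SampleSizeSpec()  # 90% Se, 85% Sp, 5% precision, 40% prevalence, 10% dropout
    n = buderer_sample_size(spec)
    print(f"Required solicited sounds at the study's design inputs: {n}")

    rows = [{"target_sensitivity": spec.target_sensitivity,
             "target_specificity": spec.target_specificity,
             "precision": spec.precision, "prevalence": spec.prevalence,
             "dropout": spec.dropout, "z": spec.z, "required_sounds": n}]
    # sensitivity of the requirement to the design precision
    for d in (0.03, 0.05, 0.08, 0.10):
        alt = SampleSizeSpec(precision=d)
        rows.append({**rows[0], "precision": d,
                     "required_sounds": buderer_sample_size(alt)})
    pd.DataFrame(rows).to_csv(OUT / "sample_size.csv", index=False)

    for v in range(1, 6):
        script = canonical_script(v)
        write_script(script, OUT / f"script_v{v}.tsv")
    script = canonical_script(1)
    print(
        f"Each script: {script.n_isolated_sounds} isolated sounds "
        f"({script.composition['cough']} coughs = "
        f"{100 * script.cough_fraction:.0f}%), plus a text passage with "
        f"{script.embedded_coughs} embedded coughs -> {script.total_coughs} "
        "solicited coughs per session."
    )
    print(f"Wrote {OUT}/sample_size.csv and script_v1..5.tsv")


if __name__ == "__main__":
    main()
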