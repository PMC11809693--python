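#!/usr/bin/env python
"""Simulate the evaluation cohort: 49 ten-minute solicited-sound sessions,
two phones running the detector, three annotators.

About a fifth of the participants are simulated as producing atypical
coughs (higher annotator disagreement), mirroring how solicited coughs are
not always unanimously recognized.  Writes label tracks, detector logs and
the session manifest under results/cohort/.
"""

import dataclasses
from pathlib import Path

from coughval import synthetic_data as sd
from coughval.io_formats import read_manifest, write_manifest

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20210901  # acquisition campaign start, as a reproducible seed


def main() -> None:
    params = sd.SimulatorParams(seed=SEED, n_sessions=39)
    cohort = sd.simulate_cohort(params)

    # ten further participants whose coughs often fail unanimity
    atypical = sd.degrade_annotators(
        dataclasses.replace(params, seed=SEED + 1, n_sessions=10),
        disagreement_rate=0.55,
    )
    for i, ses in enumerate(atypical.sessions, start=40):
        ses.truth.session_id = f"s{i:02d}"
        ses.manifest_entry["session_id"] = f"s{i:02d}"
        ses.manifest_entry["participant_id"] = f"p{i:02d}"
        cohort.sessions.append(ses)

    manifest = sd.write_cohort(cohort, OUT)
    n_coughs = sum(s.truth.n_true_coughs for s in cohort.sessions)
    print(f"Simulated {len(cohort.sessions)} sessions "
          f"({n_coughs} true solicited coughs) under {OUT}")
    print(f"Manifest: {manifest}")


if __name__ == "__main__":
    main()
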