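"""Solicited-sound session scripts and diagnostic-accuracy sample sizes.

A session script prompts the participant through a fixed composition of
explosive sounds - by default 18 isolated coughs, 10 sneezes, 5 throat
clears and 13 short words (46 isolated sounds, 39% coughs), plus one read
text passage with 2 embedded coughs (20 solicited coughs in total) - each
separated by at least 5 s of silence.  Five canonical shuffles of that
composition are provided; the version number doubles as the shuffle seed.

The sample-size computation follows the Buderer approach for sensitivity
and specificity studies: the binomial sample size for estimating the target
proportion to the stated precision, inflated by the (cough) prevalence for
the sensitivity branch (1 - prevalence for specificity) and by the dropout
rate, taking the larger branch.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Instruction",
    "ScriptSpec",
    "SampleSizeSpec",
    "DEFAULT_COMPOSITION",
    "generate_script",
    "canonical_script",
    "buderer_sample_size",
    "write_script",
    "read_script",
]

SOUND_KINDS = ("cough", "sneeze", "throat_clear", "word")
TEXT_PASSAGE = "text_passage"
MIN_GAP = 5.0

DEFAULT_COMPOSITION: dict[str, int] = {
    "cough": 18,
    "sneeze": 10,
    "throat_clear": 5,
    "word": 13,
}
DEFAULT_EMBEDDED_COUGHS = 2


@dataclass(frozen=True)
class Instruction:
    kind: str
    planned_gap: float = MIN_GAP

    def __post_init__(self) -> None:
        if self.kind not in SOUND_KINDS and self.kind != TEXT_PASSAGE:
            raise ValueError(f"unknown sound kind {self.kind!r}")
        if self.planned_gap < MIN_GAP:
            raise ValueError(f"planned gap {self.planned_gap} below minimum {MIN_GAP} s")


@dataclass
class ScriptSpec:
    """One ordered version of the solicited-sound script."""

    version: int
    instructions: list[Instruction]
    composition: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    embedded_coughs: int = DEFAULT_EMBEDDED_COUGHS

    def __post_init__(self) -> None:
        if not 1 <= self.version <= 5:
            raise ValueError(f"script version must be 1..5, got {self.version}")
        if any(n < 0 for n in self.composition.values()) or self.embedded_coughs < 0:
            raise ValueError("composition counts must be non-negative")
        counted: dict[str, int] = {}
        for ins in self.instructions:
            if ins.kind != TEXT_PASSAGE:
                counted[ins.kind] = counted.get(ins.kind, 0) + 1
        expected = {k: v for k, v in self.composition.items() if v > 0}
        if counted != expected:
            raise ValueError(
                f"instruction multiset {counted} does not match composition {expected}"
            )

    @property
    def n_isolated_sounds(self) -> int:
        return sum(self.composition.values())

    @property
    def total_coughs(self) -> int:
        """All solicited coughs, isolated plus embedded in the text passage."""
        return self.composition.get("cough", 0) + self.embedded_coughs

    @property
    def cough_fraction(self) -> float:
        """Fraction of isolated solicited sounds that are coughs."""
        return self.composition.get("cough", 0) / self.n_isolated_sounds


def generate_script(
    version_seed: int,
    composition: Mapping[str, int] | None = None,
    planned_gap: float = MIN_GAP,
    embedded_coughs: int = DEFAULT_EMBEDDED_COUGHS,
) -> ScriptSpec:
    """Deterministic shuffle of the composition for a given seed.

    The same seed always yields the same script; different seeds yield the
    same multiset of instructions in a different order.  Seeds 1-5 are the
    canonical script versions.
    """
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    unknown = set(comp) - set(SOUND_KINDS)
    if unknown:
        raise ValueError(f"unknown sound kinds in composition: {sorted(unknown)}")
    if any(n < 0 for n in comp.values()) or sum(comp.values()) == 0:
        raise ValueError(f"invalid composition {comp}")
    rng = np.random.default_rng(version_seed)
    kinds = [k for k in SOUND_KINDS for _ in range(comp.get(k, 0))]
    order = [kinds[i] for i in rng.permutation(len(kinds))]
    instructions = [Instruction(k, planned_gap) for k in order]
    # the read text passage slots in at a seeded position
    pos = int(rng.integers(0, len(instructions) + 1))
    instructions.insert(pos, Instruction(TEXT_PASSAGE, planned_gap))
    version = (int(version_seed) - 1) % 5 + 1
    return ScriptSpec(version, instructions, comp, embedded_coughs)


def canonical_script(version: int) -> ScriptSpec:
    """One of the five canonical script versions (seed = version number)."""
    if not 1 <= version <= 5:
        raise ValueError(f"canonical versions are 1..5, got {version}")
    return generate_script(version)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the sample-size computation (defaults: the study's values)."""

    target_sensitivity: float = 0.90
    target_specificity: float = 0.85
    precision: float = 0.05
    prevalence: float = 0.40
    dropout: float = 0.10
    z: float = 1.96

    def __post_init__(self) -> None:
        for name in ("target_sensitivity", "target_specificity", "precision"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.prevalence <= 1:
            raise ValueError(f"prevalence must be in (0, 1], got {self.prevalence}")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.z <= 0:
            raise ValueError(f"z must be positive, got {self.z}")


def buderer_sample_size(spec: SampleSizeSpec) -> int:
    """Required number of solicited sounds.

    Per branch: n = z^2 * p * (1-p) / d^2, divided by the branch prevalence
    and by (1 - dropout), ceiling of the larger branch.  With prevalence 1
    there are no non-cough sounds and only the sensitivity branch applies.
    """
    z2 = spec.z**2
    d2 = spec.precision**2
    retain = 1.0 - spec.dropout
    se = spec.target_sensitivity
    branches = [z2 * se * (1 - se) / d2 / spec.prevalence / retain]
    if spec.prevalence < 1:
        sp = spec.target_specificity
        branches.append(z2 * sp * (1 - sp) / d2 / (1 - spec.prevalence) / retain)
    return math.ceil(max(branches))


def write_script(script: ScriptSpec, path: str | Path) -> None:
    """Serialize a script as tab-separated ``order, kind, gap_s``."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["order", "kind", "gap_s"])
        for i, ins in enumerate(script.instructions, start=1):
            writer.writerow([i, ins.kind, f"{ins.planned_gap:.1f}"])


def read_script(path: str | Path, version: int = 1,
                embedded_coughs: int = DEFAULT_EMBEDDED_COUGHS) -> ScriptSpec:
    instructions: list[Instruction] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for row in reader:
            if not row:
                continue
            instructions.append(Instruction(row[1], float(row[2])))
    comp = {
        k: sum(1 for ins in instructions if ins.kind == k)
        for k in SOUND_KINDS
        if any(ins.kind == k for ins in instructions)
    }
    return ScriptSpec(version, instructions, comp, embedded_coughs)
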