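"""Benchmark sample compositions and dilution algebra.

A spike-in benchmark is defined by per-sample species mass fractions
(percent of total protein mass, w/w).  Because every sample is an exact
mixture, the expected abundance ratio of any species between two samples
is the ratio of its mass fractions — the ground truth against which
quantification accuracy and precision are scored.

The bundled PYE design comprises six samples: a base pair (A/B) in which
human plasma digest contributes 90% of protein mass and yeast / E. coli
digests the remaining 10% at different A:B ratios (yeast 2:6, E. coli 8:4),
plus 1:3 and 1:9 dilutions of that pair with pure plasma digest.  Diluting
A and B identically leaves every spike ratio unchanged while pushing the
spike proteins toward the detection limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "SampleComposition",
    "DilutionSeries",
    "ExpectedRatios",
    "dilute",
    "expected_log2_ratio",
    "spike_fold",
    "pye_design",
    "load_design",
]

_SUM_TOL = 1e-9


class DesignError(ValueError):
    """Raised when a benchmark design is internally inconsistent."""


@dataclass(frozen=True)
class SampleComposition:
    """Species mass fractions of one benchmark sample.

    Fractions are percent of total protein mass (w/w) and must be
    non-negative and sum to 100.
    """

    sample_id: str
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        fr = dict(self.fractions)
        object.__setattr__(self, "fractions", fr)
        for sp, f in fr.items():
            if f < 0:
                raise DesignError(f"negative mass fraction for {sp!r} in {self.sample_id!r}")
        total = sum(fr.values())
        if abs(total - 100.0) > _SUM_TOL:
            raise DesignError(
                f"fractions of {self.sample_id!r} sum to {total!r}, expected 100"
            )

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.fractions)

    def fraction(self, species: str) -> float:
        if species not in self.fractions:
            raise DesignError(f"unknown species {species!r} in {self.sample_id!r}")
        return self.fractions[species]


@dataclass(frozen=True)
class DilutionSeries:
    """An ordered benchmark series of A/B sample pairs across dilution levels."""

    samples: tuple[SampleComposition, ...]
    diluent: SampleComposition
    pair_labels: Mapping[str, tuple[str, str]]  # level -> (sample A, sample B)
    background_species: str = "human"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair_labels", dict(self.pair_labels))
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate sample ids in series")
        species_sets = {s.species for s in self.samples} | {self.diluent.species}
        if len(species_sets) != 1:
            raise DesignError("samples and diluent must share one species set")
        for level, (a, b) in self.pair_labels.items():
            for sid in (a, b):
                if sid not in ids:
                    raise DesignError(f"pair for level {level!r} references unknown sample {sid!r}")
        # the diluent is a pure background: all mass in the background species
        if abs(self.diluent.fraction(self.background_species) - 100.0) > _SUM_TOL:
            raise DesignError("diluent must carry all mass in the background species")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.pair_labels)

    @property
    def species(self) -> frozenset[str]:
        return self.diluent.species

    @property
    def spike_species(self) -> tuple[str, ...]:
        return tuple(sorted(self.species - {self.background_species}))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    def sample(self, sample_id: str) -> SampleComposition:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise DesignError(f"unknown sample {sample_id!r}")

    def pair(self, level: str) -> tuple[SampleComposition, SampleComposition]:
        if level not in self.pair_labels:
            raise DesignError(f"unknown dilution level {level!r}")
        a, b = self.pair_labels[level]
        return self.sample(a), self.sample(b)


@dataclass(frozen=True)
class ExpectedRatios:
    """Expected A/B abundance ratio of one species at one dilution level."""

    level: str
    species: str
    linear: float
    log2: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        lg = math.log2(self.linear)
        if math.isnan(self.log2):
            object.__setattr__(self, "log2", lg)
        elif abs(self.log2 - lg) > 1e-12:
            raise DesignError("log2 inconsistent with linear ratio")


def dilute(
    base: SampleComposition,
    parts_base: float,
    parts_diluent: float,
    diluent: SampleComposition,
    sample_id: str | None = None,
) -> SampleComposition:
    """Mix `parts_base` of `base` with `parts_diluent` of `diluent` (mass balance).

    Each resulting fraction is the mass-weighted mean
    ``(parts_base*f_base + parts_diluent*f_diluent) / (parts_base + parts_diluent)``.
    """
    if parts_base <= 0:
        raise DesignError("parts_base must be > 0")
    if parts_diluent < 0:
        raise DesignError("parts_diluent must be >= 0")
    if base.species != diluent.species:
        raise DesignError("base and diluent species sets differ")
    total = parts_base + parts_diluent
    fr = {
        sp: (parts_base * base.fraction(sp) + parts_diluent * diluent.fraction(sp)) / total
        for sp in base.fractions
    }
    return SampleComposition(sample_id or base.sample_id, fr)


def expected_log2_ratio(series: DilutionSeries, level: str, species: str) -> float:
    """Expected log2(A/B) mass-fraction ratio of `species` at `level`.

    Zero for the background species at every level by construction; invariant
    across levels for spike species because A and B are diluted identically.
    """
    a, b = series.pair(level)
    fb = b.fraction(species)
    if fb == 0:
        raise DesignError(f"{species!r} fraction in {b.sample_id!r} is zero; ratio undefined")
    return math.log2(a.fraction(species) / fb)


def spike_fold(series: DilutionSeries, species: str, sample_1: str, sample_2: str) -> float:
    """Linear fold of `species` mass fraction between two samples (sample_1 / sample_2)."""
    s1 = series.sample(sample_1)
    s2 = series.sample(sample_2)
    f2 = s2.fraction(species)
    if f2 == 0:
        raise DesignError(f"{species!r} fraction in {sample_2!r} is zero; fold undefined")
    return s1.fraction(species) / f2


def load_design(source: str | Path | dict) -> DilutionSeries:
    """Build a DilutionSeries from a structured design config (YAML path or dict).

    Schema::

        species: [human, yeast, ecoli]
        background: human
        base_samples:                 # fractions in percent of protein mass
          PYE1A: {human: 90, yeast: 2, ecoli: 8}
          PYE1B: {human: 90, yeast: 6, ecoli: 4}
        dilutions:                    # derived levels: parts base : parts diluent
          PYE3: {parts_base: 1, parts_diluent: 2}
          PYE9: {parts_base: 1, parts_diluent: 8}
        pairs:                        # level -> [sample A, sample B]
          PYE1: [PYE1A, PYE1B]
          PYE3: [PYE3A, PYE3B]
          PYE9: [PYE9A, PYE9B]

    Diluted sample ids are formed by replacing the base-level prefix taken
    from the pair labels, e.g. PYE1A diluted for level PYE3 becomes PYE3A.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = source
    species = list(cfg["species"])
    background = cfg.get("background", "human")
    if background not in species:
        raise DesignError(f"background species {background!r} not in species list")
    diluent = SampleComposition(
        "diluent", {sp: (100.0 if sp == background else 0.0) for sp in species}
    )
    base = {
        sid: SampleComposition(sid, {sp: float(fr.get(sp, 0.0)) for sp in species})
        for sid, fr in cfg["base_samples"].items()
    }
    pairs: dict[str, tuple[str, str]] = {
        lvl: (str(a), str(b)) for lvl, (a, b) in cfg["pairs"].items()
    }
    base_level = next(lvl for lvl, (a, b) in pairs.items() if a in base and b in base)
    samples: list[SampleComposition] = []
    for lvl, (a_id, b_id) in pairs.items():
        if lvl == base_level:
            samples.extend([base[a_id], base[b_id]])
            continue
        dil = cfg["dilutions"][lvl]
        base_a, base_b = pairs[base_level]
        for src, out in ((base_a, a_id), (base_b, b_id)):
            samples.append(
                dilute(base[src], float(dil["parts_base"]), float(dil["parts_diluent"]),
                       diluent, sample_id=out)
            )
    return DilutionSeries(tuple(samples), diluent, pairs, background_species=background)


def pye_design() -> DilutionSeries:
    """The six-sample PYE benchmark series (bundled preset).

    PYE1 A holds 90% human, 2% yeast, 8% E. coli protein mass; PYE1 B holds
    90% / 6% / 4%.  PYE3 and PYE9 dilute the PYE1 pair 1:3 and 1:9 (1 part
    sample + 2 or 8 parts pure plasma digest), leaving 3.3% and 1.1% of
    non-human protein mass respectively.
    """
    with resources.files("pyebench.presets").joinpath("pye_design.yaml").open() as fh:
        return load_design(yaml.safe_load(fh))
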