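"""ddPCR-side MRD quantification and relapse calling.

An assay's limit of detection (LoD) is estimated from wildtype-DNA wells as
``mean + 3.08 * sigma`` (one-tailed, alpha = 0.001).  When DNA input rather
than the assay limits sensitivity, the rule of three (RoT) sets the floor:
with zero mutant events in ``n`` assessable alleles the 95 % bound on the
event rate is about ``3 / n``.

MRD positivity is a detected VAF at or above the operative threshold; an MRD
relapse is either a confirmed conversion from negativity to positivity or a
>= 10-fold VAF rise between two positive samples, with the first sample
indicating relapse taken as the detection time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DdpcrAssay",
    "MrdSample",
    "MrdSeries",
    "MrdCall",
    "compute_lod",
    "rot_threshold",
    "classify_sample",
    "call_relapse",
    "lead_time",
]

LOD_Z = 3.08  # one-tailed z for alpha = 0.001


def compute_lod(wildtype_wells: Sequence[float], z: float = LOD_Z) -> float:
    """LoD (VAF %) = mean + z * sample standard deviation of wildtype wells.

    The sample standard deviation uses the n-1 denominator.  At least two
    wells are required (assay validation uses 20).
    """
    wells = np.asarray(wildtype_wells, dtype=float)
    if wells.size < 2:
        raise ValueError("LoD estimation requires >= 2 wildtype wells")
    return float(wells.mean() + z * wells.std(ddof=1))


def rot_threshold(assessable_alleles: int) -> float:
    """Rule-of-three VAF threshold in percent: ``100 * 3 / n``."""
    if assessable_alleles <= 0:
        raise ValueError("assessable allele count must be positive")
    return 300.0 / assessable_alleles


def classify_sample(
    measured_vaf: float,
    lod: float,
    rot: float | None = None,
    dna_limited: bool = False,
    positive_at_threshold: bool = True,
) -> bool:
    """MRD positivity for one sample.

    The operative threshold is the LoD, lifted to the RoT when DNA input is
    limiting and the RoT exceeds the LoD.  A VAF exactly at the threshold is
    positive by default (the positivity definition is ``VAF >= LoD``); an
    undetected VAF (0) is always negative.
    """
    threshold = lod
    if dna_limited and rot is not None and rot > lod:
        threshold = rot
    if measured_vaf <= 0:
        return False
    if positive_at_threshold:
        return measured_vaf >= threshold
    return measured_vaf > threshold


@dataclass
class DdpcrAssay:
    """A validated patient-specific ddPCR assay."""

    target: str
    wildtype_well_vafs: tuple[float, ...] = ()
    lod_override: float | None = None

    @property
    def lod(self) -> float:
        if self.lod_override is not None:
            return self.lod_override
        return compute_lod(self.wildtype_well_vafs)

    def __post_init__(self) -> None:
        if self.lod_override is None and len(self.wildtype_well_vafs) < 2:
            raise ValueError("assay needs wildtype wells or a validated LoD")
        if self.wildtype_well_vafs and self.lod_override is None:
            assert self.lod >= float(np.mean(self.wildtype_well_vafs))


@dataclass
class MrdSample:
    day: int
    tissue: str  # "PB" or "BM"
    vaf: float  # percent
    assessable_alleles: int | None = None
    dna_limited: bool = False
    positive: bool = False


@dataclass
class MrdSeries:
    """Time-ordered MRD measurements for one target, tissues merged."""

    samples: list[MrdSample]
    lod: float

    def __post_init__(self) -> None:
        for tissue in {s.tissue for s in self.samples}:
            days = [s.day for s in self.samples if s.tissue == tissue]
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError(f"days not strictly increasing within {tissue}")

    @classmethod
    def from_measurements(
        cls,
        measurements: Sequence[tuple[int, str, float]],
        lod: float,
        alleles: Sequence[int | None] | None = None,
        dna_limited: Sequence[bool] | None = None,
        positive_at_threshold: bool = True,
    ) -> "MrdSeries":
        n = len(measurements)
        alleles = list(alleles) if alleles is not None else [None] * n
        limited = list(dna_limited) if dna_limited is not None else [False] * n
        samples = []
        order = np.argsort([m[0] for m in measurements], kind="stable")
        for i in order:
            day, tissue, vaf = measurements[i]
            rot = rot_threshold(alleles[i]) if alleles[i] else None
            samples.append(
                MrdSample(
                    day=day,
                    tissue=tissue,
                    vaf=vaf,
                    assessable_alleles=alleles[i],
                    dna_limited=limited[i],
                    positive=classify_sample(
                        vaf, lod, rot, limited[i], positive_at_threshold
                    ),
                )
            )
        return cls(samples=samples, lod=lod)


@dataclass
class MrdCall:
    relapse: bool
    relapse_day: int | None = None
    mechanism: str | None = None  # "conversion" or "tenfold"
    confirming_day: int | None = None


def call_relapse(series: MrdSeries, fold: float = 10.0) -> MrdCall:
    """Scan a merged chronological series for an MRD relapse.

    Conversion: the first negative-to-positive transition whose positivity is
    confirmed by any later positive sample; detection day is the day of that
    first positive.  Tenfold: the first adjacent pair of positive samples
    with a VAF ratio >= ``fold``; detection day is the second sample's day
    (the first sample *indicating* relapse).  The earlier-firing mechanism
    wins; ties go to conversion.
    """
    samples = sorted(series.samples, key=lambda s: s.day)
    pos = [s.positive for s in samples]

    conversion: tuple[int, int] | None = None  # (day, confirming day)
    for i in range(1, len(samples)):
        if pos[i] and not pos[i - 1]:
            later = [s for s in samples[i + 1 :] if s.positive]
            if later:
                conversion = (samples[i].day, later[0].day)
                break

    tenfold: int | None = None
    for i in range(1, len(samples)):
        if pos[i] and pos[i - 1] and samples[i - 1].vaf > 0:
            if samples[i].vaf >= fold * samples[i - 1].vaf:
                tenfold = samples[i].day
                break

    if conversion is not None and (tenfold is None or conversion[0] <= tenfold):
        return MrdCall(
            relapse=True,
            relapse_day=conversion[0],
            mechanism="conversion",
            confirming_day=conversion[1],
        )
    if tenfold is not None:
        return MrdCall(relapse=True, relapse_day=tenfold, mechanism="tenfold")
    return MrdCall(relapse=False)


def lead_time(
    ddpcr_day: int, comparator_days: Mapping[str, int | None]
) -> dict[str, int]:
    """Signed detection lead per comparator method (ddPCR day minus the
    comparator's first-positive day; negative means ddPCR was earlier).

    Methods that never detected MRD (``None``) are skipped.
    """
    if ddpcr_day is None:
        raise ValueError("ddPCR detection day is required")
    return {
        method: ddpcr_day - day
        for method, day in comparator_days.items()
        if day is not None
    }
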