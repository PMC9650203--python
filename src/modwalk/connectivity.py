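"""Corticospinal (CST) and corticoreticular (CRP) streamline weights and
their interhemispheric asymmetry ratios.

The asymmetry ratio is lesioned/non-lesioned hemisphere for stroke subjects
and right/left for healthy controls; a value of 1 indicates equal streamline
weights in both hemispheres, values below 1 fewer on the lesioned (or right)
side.  Streamline weights from different scanner batches are first aligned
with a simplified location-scale harmonization (each batch standardized to
the pooled per-tract mean and variance), which, like the full empirical-Bayes
procedure it stands in for, can push small weights negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateBatchError, UndefinedRatioError

TRACT_FIELDS = ("cst_lesioned", "cst_nonlesioned", "crp_lesioned", "crp_nonlesioned")


@dataclass
class StreamlineRecord:
    """Per-hemisphere streamline weights for one subject.

    For healthy subjects the right hemisphere is stored in the ``lesioned``
    slot and the left in ``nonlesioned`` (the ratio is then right/left).
    Weights may be negative after harmonization.
    """

    subject_id: str
    group: str  # 'stroke' | 'healthy'
    cst_lesioned: float
    cst_nonlesioned: float
    crp_lesioned: float
    crp_nonlesioned: float
    scanner_batch: str = "A"

    def __post_init__(self) -> None:
        if self.group not in ("stroke", "healthy"):
            raise ValueError(f"unknown group: {self.group}")


@dataclass
class AsymmetryRatios:
    asymm_cst: float
    asymm_crp: float
    orientation: str  # 'lesioned/nonlesioned' or 'right/left'


def harmonize_batches(records: list[StreamlineRecord]) -> list[StreamlineRecord]:
    """Remove scanner-batch location and scale differences per tract channel.

    Each batch's values are standardized and re-expressed on the pooled mean
    and standard deviation of that channel across all records.  With a single
    batch the output equals the input.  Batches with fewer than two records
    cannot provide a variance estimate and raise.
    """
    batches = sorted({r.scanner_batch for r in records})
    if len(batches) <= 1:
        return [replace(r) for r in records]
    counts = {b: sum(r.scanner_batch == b for r in records) for b in batches}
    small = [b for b, c in counts.items() if c < 2]
    if small:
        raise DegenerateBatchError(f"batches with fewer than 2 records: {small}")

    values = {f: np.array([getattr(r, f) for r in records]) for f in TRACT_FIELDS}
    out = [replace(r) for r in records]
    batch_of = np.array([r.scanner_batch for r in records])
    for f, v in values.items():
        pooled_mean = v.mean()
        pooled_sd = v.std(ddof=1)
        adjusted = v.astype(float).copy()
        for b in batches:
            sel = batch_of == b
            mu, sd = v[sel].mean(), v[sel].std(ddof=1)
            if sd > 0 and pooled_sd > 0:
                adjusted[sel] = pooled_mean + (v[sel] - mu) * (pooled_sd / sd)
            else:  # constant batch: location shift only
                adjusted[sel] = pooled_mean + (v[sel] - mu)
        for r, val in zip(out, adjusted):
            setattr(r, f, float(val))
    return out


def asymmetry_ratio(record: StreamlineRecord, tract: str) -> float:
    """Interhemispheric ratio for 'cst' or 'crp'."""
    if tract not in ("cst", "crp"):
        raise ValueError(f"tract must be 'cst' or 'crp', got {tract}")
    num = getattr(record, f"{tract}_lesioned")
    den = getattr(record, f"{tract}_nonlesioned")
    if den == 0:
        raise UndefinedRatioError(
            f"{record.subject_id}: zero {tract} denominator hemisphere"
        )
    return num / den


def asymmetry_ratios(record: StreamlineRecord) -> AsymmetryRatios:
    orientation = (
        "lesioned/nonlesioned" if record.group == "stroke" else "right/left"
    )
    return AsymmetryRatios(
        asymmetry_ratio(record, "cst"), asymmetry_ratio(record, "crp"), orientation
    )
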