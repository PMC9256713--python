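"""Transgene copy-number estimation from sequencing depth and from ddPCR.

Two depth-based forms are implemented.  The raw form compares
depth-and-mapping-normalised target coverage between the transgenic (gm)
and wild-type (wt) samples:

    CN_raw = ADT_gm / (D_gm * R_gm)  -  ADT_wt / (D_wt * R_wt)

where ADT is the average sequencing depth over the target element, D the
general genome depth and R the mapped-pair fraction.  The calibrated form
normalises each sample by a single-copy endogenous reference gene (e.g. the
rice sucrose-phosphate synthase gene, SPS) instead, which cancels the D*R
factors within a sample and absorbs residual library-level bias:

    CN_cal = ADT_target_gm / ADT_sps_gm  -  ADT_target_wt / ADT_sps_wt

The calibrated form is the default estimator; the raw value is reported
alongside it for diagnostics.  ddPCR copy number is the ratio of mean
quantified transgene copies to mean endogenous-reference copies across
replicates, with replicate dispersion summarised as the relative standard
deviation (sample SD / mean, in percent).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "CopyNumberResult",
    "DdpcrReplicates",
    "copy_number_calibrated",
    "copy_number_ddpcr",
    "copy_number_raw",
    "copy_number_table",
    "read_adt_tsv",
    "read_ddpcr_tsv",
    "round_half_up",
]


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding, as used for display in copy-number tables."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CopyNumberResult:
    element: str
    raw_eq: float | None
    calibrated: float
    rounded: int
    inputs: dict = field(default_factory=dict)


@dataclass
class DdpcrReplicates:
    """Quantified copy counts from replicate ddPCR reactions."""

    target: Sequence[float]
    reference: Sequence[float]

    def __post_init__(self) -> None:
        if not self.target or not self.reference:
            raise ValueError("replicate lists must be non-empty")
        if any(v < 0 for v in list(self.target) + list(self.reference)):
            raise ValueError("replicate counts must be non-negative")
        if sum(self.reference) == 0:
            raise ValueError("reference replicate mean must be positive")


def copy_number_raw(
    adt_gm: float, d_gm: float, r_gm: float,
    adt_wt: float, d_wt: float, r_wt: float,
) -> float:
    """Raw depth-normalised copy number (gm minus wt background)."""
    if d_gm * r_gm <= 0 or d_wt * r_wt <= 0:
        raise ZeroDivisionError("D * R must be positive for both samples")
    return adt_gm / (d_gm * r_gm) - adt_wt / (d_wt * r_wt)


def copy_number_calibrated(
    adt_target_gm: float, adt_sps_gm: float,
    adt_target_wt: float, adt_sps_wt: float,
) -> float:
    """Single-copy-gene calibrated copy number.

    Small negative values (wild-type background exceeding the transgenic
    signal under noise) are clipped to zero with a warning.
    """
    if adt_sps_gm <= 0:
        raise ZeroDivisionError("calibrator depth must be positive in the gm sample")
    if adt_target_wt > 0 and adt_sps_wt <= 0:
        raise ZeroDivisionError("calibrator depth must be positive in the wt sample")
    wt_term = adt_target_wt / adt_sps_wt if adt_sps_wt > 0 else 0.0
    value = adt_target_gm / adt_sps_gm - wt_term
    if value < 0:
        warnings.warn(f"negative calibrated copy number ({value:.3f}) clipped to 0")
        return 0.0
    return value


def copy_number_ddpcr(reps: DdpcrReplicates) -> tuple[float, float | None, float | None]:
    """(copy-number ratio, target RSD %, reference RSD %).

    RSD uses the sample (n-1) standard deviation and is undefined (None)
    with fewer than two replicates.
    """

    def mean(v):
        return sum(v) / len(v)

    def rsd(v):
        if len(v) < 2:
            return None
        m = mean(v)
        if m == 0:
            return None
        sd = math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))
        return sd / m * 100.0

    ratio = mean(reps.target) / mean(reps.reference)
    return ratio, rsd(reps.target), rsd(reps.reference)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def copy_number_table(
    adt_gm: dict[str, float],
    adt_wt: dict[str, float],
    d_gm: float | None = None,
    r_gm: float | None = None,
    d_wt: float | None = None,
    r_wt: float | None = None,
    calibrator: str = "SPS",
) -> list[CopyNumberResult]:
    """Per-element copy numbers from ADT maps of the two samples.

    The calibrator element must be present in ``adt_gm``; elements missing
    from the wild-type map contribute a zero background term.  When the D/R
    statistics are supplied the raw formula value is reported alongside.
    """
    if calibrator not in adt_gm:
        raise ValueError(f"calibrator element {calibrator!r} missing from gm ADT table")
    sps_gm = adt_gm[calibrator]
    sps_wt = adt_wt.get(calibrator, 0.0)
    results = []
    for element, a_gm in adt_gm.items():
        if element == calibrator:
            continue
        a_wt = adt_wt.get(element, 0.0)
        cal = copy_number_calibrated(a_gm, sps_gm, a_wt, sps_wt)
        raw = None
        if None not in (d_gm, r_gm, d_wt, r_wt):
            raw = copy_number_raw(a_gm, d_gm, r_gm, a_wt, d_wt, r_wt)
        results.append(
            CopyNumberResult(
                element=element,
                raw_eq=raw,
                calibrated=cal,
                rounded=int(round_half_up(cal, 0)),
                inputs={"adt_gm": a_gm, "adt_wt": a_wt,
                        "adt_sps_gm": sps_gm, "adt_sps_wt": sps_wt,
                        "d_gm": d_gm, "r_gm": r_gm, "d_wt": d_wt, "r_wt": r_wt},
            )
        )
    return results


def read_adt_tsv(path: str | Path) -> tuple[dict[str, float], dict[str, float]]:
    """Read ``element<TAB>adt_gm<TAB>adt_wt`` into two ADT maps (SPS row mandatory)."""
    df = pd.read_csv(path, sep="\t")
    required = {"element", "adt_gm", "adt_wt"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if "SPS" not in set(df["element"]):
        raise ValueError(f"{path}: mandatory SPS calibrator row missing")
    gm = dict(zip(df["element"], df["adt_gm"].astype(float)))
    wt = dict(zip(df["element"], df["adt_wt"].astype(float)))
    return gm, wt


def read_ddpcr_tsv(path: str | Path) -> dict[str, list[float]]:
    """Read ``element<TAB>rep1<TAB>rep2...`` into replicate-count lists."""
    out: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            out[fields[0]] = [float(v) for v in fields[1:] if v != ""]
    return out


def results_frame(results: Sequence[CopyNumberResult]) -> pd.DataFrame:
    rows = [
        {
            "element": r.element,
            "adt_gm": r.inputs.get("adt_gm"),
            "adt_wt": r.inputs.get("adt_wt"),
            "copy_number_raw": None if r.raw_eq is None else round_half_up(r.raw_eq),
            "copy_number": round_half_up(r.calibrated),
            "rounded": r.rounded,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
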