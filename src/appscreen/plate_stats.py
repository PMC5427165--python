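"""Plate-level quality control, normalization, and well filtering.

The gatekeeping stage between raw well records and gene scores:

* **SSMD (beta-score) QC** — per plate and replicate, the strictly
  standardized mean difference between each positive-control group (siAPP,
  siPSEN1) and the non-targeting group, per channel; plates pass when the
  magnitude clears a threshold (default 3) on the required channels.
* **Fold-change normalization** — every well's intensity divided by the
  mean of the included non-targeting wells on the same plate, so plate-wide
  multiplicative effects cancel.
* **Well filtering** — wells with fewer than 300 analyzable cells, and all
  sample wells of failing plates, are excluded from downstream scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (InputError, NormalizationError, QCError,
                     SSMDUndefinedError)
from .synth_screen import ROLE_NT, ROLE_SIAPP, ROLE_SIPSEN1

QC_COLUMNS = [
    "plate_id", "replicate",
    "beta_siAPP_mcherry", "beta_siAPP_yfp",
    "beta_siPSEN1_mcherry", "beta_siPSEN1_yfp",
    "passed",
]


@dataclass
class PlateQCReport:
    plate_id: str
    replicate: int
    beta_siAPP_mcherry: float
    beta_siAPP_yfp: float
    beta_siPSEN1_mcherry: float
    beta_siPSEN1_yfp: float
    passed: bool


def compute_ssmd(group_a, group_b) -> float:
    """Strictly standardized mean difference between two groups.

    SSMD = (mean_a - mean_b) / sqrt(var_a + var_b) with unbiased (n-1)
    sample variances; the sign is preserved. Raises
    :class:`SSMDUndefinedError` when both variances are zero and
    :class:`InputError` when either group has fewer than two values.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InputError(
            f"each group needs >= 2 values, got {a.size} and {b.size}")
    denom2 = a.var(ddof=1) + b.var(ddof=1)
    if denom2 == 0:
        raise SSMDUndefinedError("both groups have zero variance")
    return float((a.mean() - b.mean()) / np.sqrt(denom2))


def qc_plate(
    plate_wells: pd.DataFrame,
    threshold: float = 3.0,
    required_channels: tuple[str, ...] = ("mcherry",),
) -> PlateQCReport:
    """SSMD quality control of one plate in one replicate.

    ``plate_wells`` must contain exactly one (plate_id, replicate) group
    with its control wells. SSMD is evaluated on raw well means; the plate
    passes when ``|beta| >= threshold`` for both positive controls on every
    required channel (mCherry only by default — it is the main read-out).
    """
    plate_ids = plate_wells["plate_id"].unique()
    reps = plate_wells["replicate"].unique()
    if len(plate_ids) != 1 or len(reps) != 1:
        raise InputError("qc_plate expects one plate and one replicate")
    for ch in required_channels:
        if ch not in ("mcherry", "yfp"):
            raise InputError(f"unknown channel {ch!r}")

    groups = {}
    for role in (ROLE_NT, ROLE_SIAPP, ROLE_SIPSEN1):
        sub = plate_wells[plate_wells["role"] == role]
        if len(sub) < 2:
            raise QCError(
                f"plate {plate_ids[0]} replicate {reps[0]}: control group "
                f"{role!r} missing or too small ({len(sub)} wells)")
        groups[role] = sub

    betas = {}
    for role in (ROLE_SIAPP, ROLE_SIPSEN1):
        for ch in ("mcherry", "yfp"):
            col = f"{ch}_mean"
            try:
                betas[(role, ch)] = compute_ssmd(
                    groups[role][col], groups[ROLE_NT][col])
            except SSMDUndefinedError:
                betas[(role, ch)] = float("nan")

    passed = all(
        np.isfinite(betas[(role, ch)]) and abs(betas[(role, ch)]) >= threshold
        for role in (ROLE_SIAPP, ROLE_SIPSEN1)
        for ch in required_channels
    )
    return PlateQCReport(
        plate_id=str(plate_ids[0]),
        replicate=int(reps[0]),
        beta_siAPP_mcherry=betas[(ROLE_SIAPP, "mcherry")],
        beta_siAPP_yfp=betas[(ROLE_SIAPP, "yfp")],
        beta_siPSEN1_mcherry=betas[(ROLE_SIPSEN1, "mcherry")],
        beta_siPSEN1_yfp=betas[(ROLE_SIPSEN1, "yfp")],
        passed=bool(passed),
    )


def qc_screen(
    wells: pd.DataFrame,
    threshold: float = 3.0,
    required_channels: tuple[str, ...] = ("mcherry",),
) -> pd.DataFrame:
    """Run :func:`qc_plate` over every (plate_id, replicate) group."""
    reports = [
        qc_plate(group, threshold=threshold,
                 required_channels=required_channels)
        for _, group in wells.groupby(["plate_id", "replicate"], sort=True)
    ]
    return pd.DataFrame([vars(r) for r in reports], columns=QC_COLUMNS)


def filter_wells(
    wells: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    min_cells: int = 300,
) -> pd.DataFrame:
    """Set the ``included`` flag: enough analyzable cells and a passing plate.

    A well is included when ``cell_count >= min_cells`` and its
    (plate, replicate) passed QC. With ``qc=None`` every plate is treated
    as passing (useful for unit-scale data without control wells).
    """
    out = wells.copy()
    ok_count = out["cell_count"] >= min_cells
    if qc is None:
        plate_ok = pd.Series(True, index=out.index)
    else:
        passed = qc.set_index(["plate_id", "replicate"])["passed"]
        key = pd.MultiIndex.from_frame(out[["plate_id", "replicate"]])
        plate_ok = pd.Series(
            passed.reindex(key).fillna(False).to_numpy(), index=out.index)
    out["included"] = (ok_count & plate_ok).to_numpy()
    return out


def normalize_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Fill per-channel fold-changes against the plate's non-targeting mean.

    For each (plate_id, replicate): ``fc = well_mean / mean(included NT
    well means)``, per channel, for every well on the plate (non-targeting
    wells receive fold-changes too, so their mean fold-change is 1 by
    construction). Plates whose non-targeting wells are all excluded raise
    :class:`NormalizationError` if they still carry included wells;
    otherwise their fold-changes are left NaN.
    """
    if "included" not in wells.columns:
        wells = wells.assign(included=True)
    out = wells.copy()
    out["mcherry_fc"] = np.nan
    out["yfp_fc"] = np.nan
    for (plate, rep), idx in out.groupby(
            ["plate_id", "replicate"], sort=False).groups.items():
        group = out.loc[idx]
        nt = group[(group["role"] == ROLE_NT) & group["included"]]
        if len(nt) == 0:
            if group["included"].any():
                raise NormalizationError(
                    f"plate {plate} replicate {rep}: no included "
                    "non-targeting wells to normalize against")
            continue
        for ch in ("mcherry", "yfp"):
            ref = nt[f"{ch}_mean"].mean()
            if ref <= 0:
                raise NormalizationError(
                    f"plate {plate} replicate {rep}: non-positive "
                    f"non-targeting mean on {ch}")
            out.loc[idx, f"{ch}_fc"] = group[f"{ch}_mean"] / ref
    return out


def process_wells(
    wells: pd.DataFrame,
    min_cells: int = 300,
    ssmd_threshold: float = 3.0,
    required_channels: tuple[str, ...] = ("mcherry",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC -> filter -> normalize in the canonical order.

    Returns ``(normalized wells, qc table)``.
    """
    qc = qc_screen(wells, threshold=ssmd_threshold,
                   required_channels=required_channels)
    flagged = filter_wells(wells, qc, min_cells=min_cells)
    return normalize_wells(flagged), qc
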