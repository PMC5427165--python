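"""Intensity-level simulator of complete triplicate genome-scale screens.

Bypasses images entirely: each well's mean reporter intensity is drawn
directly, so plate QC, normalization and hit calling can be exercised at
the full ~18k-gene, 384-well, triplicate scale in seconds.

Well model (per channel):

    intensity = baseline * 2**gene_effect * plate_factor * well_noise

where the plate factor and well noise are unit-mean log-normal with the
configured coefficients of variation. Control wells replace the gene term
with a per-control multiplicative factor: the siAPP positive control
suppresses both reporters, the siPSEN1 control (a gamma-secretase subunit)
raises them by blocking clearance of the intracellular fragments, and the
non-targeting control is neutral. Cell counts come from the calibrated
truncated normal in :mod:`appscreen.cellcounts`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellcounts import DEFAULT_MEAN, DEFAULT_SD, sample_cell_counts
from .errors import CapacityError, InputError

ROLE_SAMPLE = "sample"
ROLE_NT = "non_targeting"
ROLE_SIAPP = "siAPP"
ROLE_SIPSEN1 = "siPSEN1"
CONTROL_ROLES = (ROLE_NT, ROLE_SIAPP, ROLE_SIPSEN1)

WELL_COLUMNS = [
    "plate_id", "well", "replicate", "sirna_id", "role",
    "cell_count", "mcherry_mean", "yfp_mean",
]

_PLATE_SHAPES = {384: (16, 24), 96: (8, 12)}


@dataclass
class GeneEffect:
    """True multiplicative effect of silencing one gene, in log2 units."""

    gene_id: str
    mcherry_log2_effect: float = 0.0
    yfp_log2_effect: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mcherry_log2_effect)
                and math.isfinite(self.yfp_log2_effect)):
            raise InputError(f"non-finite effect for {self.gene_id}")


@dataclass
class ScreenSimConfig:
    n_genes: int = 2000
    plate_size: int = 384
    n_replicates: int = 3
    n_nt_wells_per_plate: int = 14
    n_siapp_wells_per_plate: int = 14
    n_sipsen1_wells_per_plate: int = 14
    baseline_mcherry: float = 500.0
    baseline_yfp: float = 300.0
    well_noise_cv: float = 0.1
    plate_effect_cv: float = 0.05
    cellcount_mean: float = DEFAULT_MEAN
    cellcount_sd: float = DEFAULT_SD
    # role -> (mcherry factor, yfp factor); repo defaults, strong enough
    # that the expected plate SSMD magnitude sits well clear of 3 at the
    # default noise with n=14 wells per control
    control_effects: dict = field(default_factory=lambda: {
        ROLE_SIAPP: (0.4, 0.4),
        ROLE_SIPSEN1: (2.2, 1.9),
    })
    n_plates: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_replicates < 1:
            raise InputError("need n_genes >= 0 and n_replicates >= 1")
        if self.plate_size not in _PLATE_SHAPES:
            raise InputError(
                f"unsupported plate_size {self.plate_size}; "
                f"known: {sorted(_PLATE_SHAPES)}")
        if min(self.well_noise_cv, self.plate_effect_cv) < 0:
            raise InputError("noise CVs must be >= 0")
        if self.n_controls >= self.plate_size:
            raise InputError("control wells must fit within the plate")
        for role, factors in self.control_effects.items():
            if role not in (ROLE_SIAPP, ROLE_SIPSEN1):
                raise InputError(f"unknown control role {role!r}")
            if min(factors) <= 0:
                raise InputError(f"control factors must be > 0: {factors}")

    @property
    def n_controls(self) -> int:
        return (self.n_nt_wells_per_plate + self.n_siapp_wells_per_plate
                + self.n_sipsen1_wells_per_plate)

    @property
    def sample_wells_per_plate(self) -> int:
        return self.plate_size - self.n_controls


def well_names(plate_size: int) -> list[str]:
    """Well ids (A1..P24 for 384) in column-major order: controls and genes
    fill the plate column by column from the left edge."""
    n_rows, n_cols = _PLATE_SHAPES[plate_size]
    rows = [chr(ord("A") + i) for i in range(n_rows)]
    return [f"{r}{c}" for c in range(1, n_cols + 1) for r in rows]


def make_layouts(config: ScreenSimConfig, gene_ids: list[str]
                 ) -> pd.DataFrame:
    """Assign genes and controls to plates and wells.

    Controls occupy the first wells in column-major order (the left-edge
    columns), cycling NT / siAPP / siPSEN1 so no control is confounded with
    a single column; genes fill the remaining wells in order. The layout is
    identical across replicates.
    """
    per_plate = config.sample_wells_per_plate
    n_plates = math.ceil(len(gene_ids) / per_plate) if gene_ids else 1
    if config.n_plates is not None:
        if config.n_plates * per_plate < len(gene_ids):
            raise CapacityError(
                f"{len(gene_ids)} genes need "
                f"{math.ceil(len(gene_ids) / per_plate)} plates of "
                f"{per_plate} sample wells; only {config.n_plates} configured")
        n_plates = config.n_plates

    names = well_names(config.plate_size)
    control_cycle: list[str] = []
    remaining = {
        ROLE_NT: config.n_nt_wells_per_plate,
        ROLE_SIAPP: config.n_siapp_wells_per_plate,
        ROLE_SIPSEN1: config.n_sipsen1_wells_per_plate,
    }
    while any(remaining.values()):
        for role in CONTROL_ROLES:
            if remaining[role] > 0:
                control_cycle.append(role)
                remaining[role] -= 1

    rows = []
    gene_iter = iter(gene_ids)
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        for i, well in enumerate(names):
            if i < len(control_cycle):
                role = control_cycle[i]
                rows.append((plate_id, well, role, role))
            else:
                gene = next(gene_iter, None)
                if gene is None:
                    break
                rows.append((plate_id, well, gene, ROLE_SAMPLE))
    return pd.DataFrame(rows, columns=["plate_id", "well", "sirna_id", "role"])


def _unit_lognormal(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean log-normal factors with the given CV (exactly 1 at cv=0)."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv ** 2)
    return rng.lognormal(-s2 / 2, np.sqrt(s2), size=size)


def spike_controls(config: ScreenSimConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Control well intensities for one plate and replicate.

    Returns one row per control well (role, mcherry_mean, yfp_mean): the
    baseline scaled by the role's configured factors plus well noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    rows = []
    counts = {
        ROLE_NT: config.n_nt_wells_per_plate,
        ROLE_SIAPP: config.n_siapp_wells_per_plate,
        ROLE_SIPSEN1: config.n_sipsen1_wells_per_plate,
    }
    for role, n in counts.items():
        f_mch, f_yfp = (1.0, 1.0) if role == ROLE_NT \
            else config.control_effects[role]
        noise_m = _unit_lognormal(config.well_noise_cv, n, rng)
        noise_y = _unit_lognormal(config.well_noise_cv, n, rng)
        for k in range(n):
            rows.append((role,
                         config.baseline_mcherry * f_mch * noise_m[k],
                         config.baseline_yfp * f_yfp * noise_y[k]))
    return pd.DataFrame(rows, columns=["role", "mcherry_mean", "yfp_mean"])


def simulate_screen(
    config: ScreenSimConfig,
    effects: list[GeneEffect],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate all plates of a replicated screen.

    Returns ``(wells, layout)``: ``wells`` has one row per well per
    replicate with the :data:`WELL_COLUMNS` schema; ``layout`` is the
    replicate-independent plate map. Deterministic under ``config.seed``.
    """
    if len(effects) != config.n_genes:
        raise InputError(
            f"effects cover {len(effects)} genes, config says {config.n_genes}")
    gene_ids = [e.gene_id for e in effects]
    if len(set(gene_ids)) != len(gene_ids):
        raise InputError("duplicate gene ids in effects")
    layout = make_layouts(config, gene_ids)

    rng = np.random.default_rng(config.seed)
    mch_fx = {e.gene_id: 2.0 ** e.mcherry_log2_effect for e in effects}
    yfp_fx = {e.gene_id: 2.0 ** e.yfp_log2_effect for e in effects}
    for role in CONTROL_ROLES:
        f = (1.0, 1.0) if role == ROLE_NT else config.control_effects[role]
        mch_fx[role], yfp_fx[role] = f

    gene_mch = layout["sirna_id"].map(mch_fx).to_numpy()
    gene_yfp = layout["sirna_id"].map(yfp_fx).to_numpy()
    plate_ids = layout["plate_id"].to_numpy()
    plates = pd.unique(plate_ids)

    frames = []
    for rep in range(1, config.n_replicates + 1):
        pf_m = dict(zip(plates, _unit_lognormal(
            config.plate_effect_cv, len(plates), rng)))
        pf_y = dict(zip(plates, _unit_lognormal(
            config.plate_effect_cv, len(plates), rng)))
        plate_m = np.array([pf_m[p] for p in plate_ids])
        plate_y = np.array([pf_y[p] for p in plate_ids])
        n = len(layout)
        noise_m = _unit_lognormal(config.well_noise_cv, n, rng)
        noise_y = _unit_lognormal(config.well_noise_cv, n, rng)
        rep_df = layout.copy()
        rep_df["replicate"] = rep
        rep_df["cell_count"] = sample_cell_counts(
            n, rng, mean=config.cellcount_mean, sd=config.cellcount_sd)
        rep_df["mcherry_mean"] = (
            config.baseline_mcherry * gene_mch * plate_m * noise_m)
        rep_df["yfp_mean"] = (
            config.baseline_yfp * gene_yfp * plate_y * noise_y)
        frames.append(rep_df)

    wells = pd.concat(frames, ignore_index=True)[WELL_COLUMNS]
    return wells, layout


def sample_gene_effects(
    n_genes: int,
    active_fraction: float = 0.05,
    effect_size: float = 1.0,
    yfp_coupling: float = 0.6,
    seed: int = 0,
) -> list[GeneEffect]:
    """Draw a gene-effect panel for simulation studies.

    ``active_fraction`` of genes carry a true effect of magnitude
    ``effect_size`` (log2 units) on mCherry, split evenly between up- and
    down-regulation as in a two-tailed screen design; the YFP effect is the
    mCherry effect scaled by ``yfp_coupling`` (the YFP reporter responds
    more weakly). The rest are true nulls.
    """
    if not 0 <= active_fraction <= 1:
        raise InputError("active_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_active = int(round(n_genes * active_fraction))
    active = rng.choice(n_genes, size=n_active, replace=False)
    signs = np.zeros(n_genes)
    half = n_active // 2
    signs[active[:half]] = 1.0
    signs[active[half:]] = -1.0
    effects = []
    for i in range(n_genes):
        e = signs[i] * effect_size
        effects.append(GeneEffect(
            gene_id=f"GENE{i + 1:06d}",
            mcherry_log2_effect=e,
            yfp_log2_effect=e * yfp_coupling,
        ))
    return effects
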