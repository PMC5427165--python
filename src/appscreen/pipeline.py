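"""End-to-end orchestration: simulate -> QC -> normalize -> hits -> xref.

Every stage writes its result as a delimited text table in the output
directory, and a manifest records a SHA-256 digest of each output so that
end-to-end determinism under a fixed seed is checkable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetics_xref, hit_calling, image_quant, plate_stats
from . import synth_microscopy, synth_screen
from .errors import InputError

log = logging.getLogger("appscreen")


@dataclass
class PipelineConfig:
    """Validated configuration for the full pipeline.

    Houses the screen's fixed analysis constants — the 300-cell
    analyzability floor, the SSMD threshold of 3, the 2.5% hit tails —
    in one place, plus the simulator sections. Unknown keys are rejected.
    """

    seed: int = 0
    output_dir: str = "appscreen_out"
    min_cells: int = 300
    ssmd_threshold: float = 3.0
    tail_fraction: float = 0.025
    min_replicates: int = 2
    channel: str = "mcherry"
    family_alpha: float = 0.05
    screen_sim: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    image_sim: dict = field(default_factory=dict)
    n_image_wells: int = 4
    locus_genes_path: str | None = None
    association_table_path: str | None = None

    def __post_init__(self) -> None:
        if self.min_cells < 0:
            raise InputError("min_cells must be >= 0")
        if self.ssmd_threshold < 0:
            raise InputError("ssmd_threshold must be >= 0")
        if not 0 < self.tail_fraction < 0.5:
            raise InputError("tail_fraction must be in (0, 0.5)")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # validate the simulator sections eagerly so bad keys fail here
        cfg.screen_config()
        synth_microscopy.ImageSimParams(**cfg.image_sim)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def screen_config(self, seed: int | None = None
                      ) -> synth_screen.ScreenSimConfig:
        kwargs = dict(self.screen_sim)
        if seed is not None:
            kwargs["seed"] = seed
        try:
            return synth_screen.ScreenSimConfig(**kwargs)
        except TypeError as exc:
            raise InputError(f"bad screen_sim section: {exc}") from exc


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the intensity-level screen end-to-end and write all outputs.

    Returns a result bundle with the in-memory tables and the output
    manifest. Identical config and seed give byte-identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    seed_effects, seed_sim = (int(s % (2 ** 31)) for s in ss.generate_state(2))

    sim_cfg = config.screen_config(seed=seed_sim)
    effects = synth_screen.sample_gene_effects(
        sim_cfg.n_genes, seed=seed_effects, **config.effects)
    log.info("simulating %d genes x %d replicates",
             sim_cfg.n_genes, sim_cfg.n_replicates)
    wells, layout = synth_screen.simulate_screen(sim_cfg, effects)

    log.info("plate QC and normalization")
    normalized, qc = plate_stats.process_wells(
        wells, min_cells=config.min_cells,
        ssmd_threshold=config.ssmd_threshold)

    log.info("aggregating replicates and calling hits")
    scores, dropped = hit_calling.aggregate_replicates(
        normalized, min_replicates=config.min_replicates)
    params = hit_calling.HitCallingParams(
        tail_fraction=config.tail_fraction, channel=config.channel,
        min_replicates=config.min_replicates)
    scored, hit_table = hit_calling.call_hits(scores, params)
    robustness = hit_calling.robustness_report(scored)

    log.info("GWAS-locus cross-reference")
    if config.locus_genes_path:
        locus_genes = genetics_xref.read_locus_genes(config.locus_genes_path)
    else:
        locus_genes = genetics_xref.load_locus_genes()
    overlap = genetics_xref.crossref_hits(hit_table, locus_genes)
    if config.association_table_path:
        assoc = genetics_xref.validate_associations(
            pd.read_csv(config.association_table_path))
    else:
        assoc = genetics_xref.load_association_fixture()
    bonf = genetics_xref.bonferroni_filter(
        assoc, family_alpha=config.family_alpha)

    tables = {
        "plate_map.csv": layout,
        "wells.csv": normalized,
        "qc.csv": qc,
        "gene_scores.csv": scored,
        "hits.csv": hit_table,
        "dropped_genes.csv": dropped,
        "locus_overlap.csv": overlap,
        "bonferroni_survivors.csv": bonf.survivors,
    }
    for name, df in tables.items():
        _write_csv(df, out / name)

    summary = {
        "seed": config.seed,
        "n_genes_scored": int(len(scored)),
        "n_hits": int(len(hit_table)),
        "n_dropped": int(len(dropped)),
        "plates_passed": int(qc["passed"].sum()),
        "plates_total": int(len(qc)),
        "bonferroni_threshold": bonf.threshold,
        "bonferroni_threshold_display": bonf.threshold_display,
        "bonferroni_survivors": bonf.survivors["gene"].tolist(),
        "robustness": robustness,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = {
        "outputs": {name: _sha256(out / name)
                    for name in [*tables, "summary.json"]},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "wells": normalized,
        "qc": qc,
        "scores": scored,
        "hits": hit_table,
        "dropped": dropped,
        "overlap": overlap,
        "bonferroni": bonf,
        "robustness": robustness,
        "summary": summary,
        "manifest": manifest,
        "output_dir": out,
    }


def simulate_image_wells(config: PipelineConfig, out_dir: str | Path
                         ) -> pd.DataFrame:
    """Render ``n_image_wells`` synthetic wells to TIFF plus ground truth.

    Returns the written plate map (one sample well per image; the
    image-path demo does not lay out control wells).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = synth_microscopy.ImageSimParams(
        **{**config.image_sim, "seed": config.seed})
    rng = np.random.default_rng(params.seed)
    rows = []
    names = synth_screen.well_names(384)
    for i in range(config.n_image_wells):
        well_id = f"P001_{names[i]}"
        stack, cells = synth_microscopy.simulate_well(
            params, well_id=well_id, rng=rng)
        synth_microscopy.write_well(stack, cells, out_dir)
        rows.append(("P001", names[i], f"GENE{i + 1:06d}", "sample"))
    plate_map = pd.DataFrame(
        rows, columns=["plate_id", "well", "sirna_id", "role"])
    plate_map.to_csv(out_dir / "plate_map.csv", index=False)
    return plate_map


def quantify_image_dir(
    images_dir: str | Path,
    plate_map: pd.DataFrame,
    quant_config: image_quant.QuantConfig | None = None,
    replicate: int = 1,
) -> pd.DataFrame:
    """Quantify every mapped well image into the standard well table."""
    images_dir = Path(images_dir)
    rows = []
    for _, entry in plate_map.iterrows():
        well_id = f"{entry.plate_id}_{entry.well}"
        tiff = images_dir / f"{well_id}.tiff"
        if not tiff.exists():
            raise InputError(f"missing image for well {well_id}: {tiff}")
        stack = image_quant.read_well_tiff(tiff)
        seg = image_quant.segment_well(stack, quant_config)
        record, _ = image_quant.quantify_well(stack, seg, quant_config)
        rows.append({
            "plate_id": entry.plate_id,
            "well": entry.well,
            "replicate": replicate,
            "sirna_id": entry.sirna_id,
            "role": entry.role,
            "cell_count": record["cell_count"],
            "mcherry_mean": record["mcherry_mean"],
            "yfp_mean": record["yfp_mean"],
        })
    return pd.DataFrame(rows, columns=synth_screen.WELL_COLUMNS)
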