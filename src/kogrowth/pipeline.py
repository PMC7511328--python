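"""End-to-end orchestration: growth -> classes/enrichment -> DEG/DGG ->
association -> periodicity, from on-disk tables to TSV outputs plus a JSON
manifest recording parameters, seeds and row counts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, differential, fitness, growth, io, periodicity
from .errors import KogrowthError

__all__ = ["PipelineConfig", "run_pipeline", "simulate_to_dir"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and analysis parameters driving :func:`run_pipeline`."""

    annotation: str
    well_map: str
    plate_dir: str
    out_dir: str
    expression: dict[str, str] = field(default_factory=dict)  # medium -> TSV
    media: tuple[str, str] = ("LB", "M63")
    window_kb: int = 100
    bin_step_kb: int = 1
    rate_window: int = 5
    floor: float = growth.DEFAULT_FLOOR
    n_perm: int = 1000
    n_shuffles: int = 1000
    q_threshold: float = 0.05
    min_genes: int = 30
    exclude_k1: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def simulate_to_dir(config, out_dir: str | Path) -> dict:
    """Write a full synthetic input set (annotation, expression, plates, map).

    ``config`` is a :class:`kogrowth.synthetic.SyntheticConfig`.  Returns the
    paths written, suitable for seeding a :class:`PipelineConfig`.
    """
    from . import synthetic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = synthetic.generate_annotation(config)
    io.write_annotation(ann, out / "annotation.tsv")
    paths = {"annotation": str(out / "annotation.tsv"), "expression": {}}
    maps = []
    nonessential = ann.loc[~ann["essential"], "gene"].tolist()
    for spec in config.media:
        expr = synthetic.generate_expression(ann, config, spec.name)
        expr_path = out / f"expression_{spec.name}.tsv"
        io.write_expression(expr.drop(columns=["mean"]), expr_path)
        paths["expression"][spec.name] = str(expr_path)
        truth = synthetic.generate_growth_truth(ann, expr, config, spec.name)
        truth.to_csv(out / f"truth_{spec.name}.tsv", sep="\t", index=False,
                     float_format="%.6g")
        layout = synthetic.default_layout(nonessential, spec.name, config.n_replicates)
        curves = synthetic.generate_plate_curves(truth, config, layout)
        plate_dir = out / "plates"
        plate_dir.mkdir(exist_ok=True)
        for plate in layout["plate"].unique():
            io.write_plate_csv(curves, plate, plate_dir / f"{plate}.csv")
        maps.append(layout)
    well_map = pd.concat(maps, ignore_index=True)
    io.write_well_map(well_map, out / "well_map.csv")
    paths["well_map"] = str(out / "well_map.csv")
    paths["plate_dir"] = str(out / "plates")
    return paths


def _growth_stage(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    well_map = io.read_well_map(cfg.well_map)
    estimates = []
    for plate in well_map["plate"].unique():
        csv = Path(cfg.plate_dir) / f"{plate}.csv"
        curves = io.read_plate_csv(csv, well_map[well_map["plate"] == plate], plate)
        estimates.extend(
            growth.estimate_growth_rate(c, window=cfg.rate_window, floor=cfg.floor)
            for c in curves
        )
    rate_table = growth.aggregate_replicates(estimates)
    return rate_table, growth.estimates_frame(estimates)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage the inputs allow; write TSVs and a JSON manifest.

    Stages needing expression tables are skipped with a notice when
    ``cfg.expression`` is empty.  Any stage error aborts with the stage name;
    outputs written so far stay on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(cfg), "stages": {}, "seed": cfg.seed}
    stage = "annotation"
    try:
        ann = io.read_annotation(cfg.annotation)
        L = ann.attrs["genome_length_kb"]
        manifest["stages"][stage] = {"status": "ok", "n_genes": len(ann)}

        stage = "growth"
        rate_table, est_frame = _growth_stage(cfg)
        io.write_rate_table(rate_table, out / "rate_table.tsv")
        est_frame.to_csv(out / "replicate_estimates.tsv", sep="\t", index=False,
                         float_format="%.6g")
        manifest["stages"][stage] = {"status": "ok", "n_strains": int(rate_table["strain"].nunique())}

        stage = "classification"
        assignments = {}
        nonessential_bg = ann[~ann["essential"]]
        for medium in cfg.media:
            cls = fitness.classify_genes(rate_table, medium)
            assignments[medium] = cls
            cls.to_csv(out / f"classes_{medium}.tsv", sep="\t", index=False,
                       float_format="%.6g")
            vp = set(cls.loc[cls["fitness_class"] == "very_positive", "strain"])
            if vp:
                enr = fitness.binomial_enrichment(vp, ann, background=nonessential_bg)
                enr.to_csv(out / f"enrichment_very_positive_{medium}.tsv",
                           sep="\t", index=False, float_format="%.6g")
        overlap = fitness.class_overlap(
            assignments[cfg.media[0]], assignments[cfg.media[1]], "very_positive"
        )
        manifest["stages"][stage] = {
            "status": "ok",
            "very_positive_overlap": {k: overlap[k] for k in ("only_a", "only_b", "both")},
        }

        have_expression = all(m in cfg.expression for m in cfg.media)
        if have_expression:
            stage = "normalization"
            tables = [io.read_expression(cfg.expression[m]) for m in cfg.media]
            tables = differential.global_normalize(tables)
            for m, t in zip(cfg.media, tables):
                io.write_expression(t, out / f"expression_norm_{m}.tsv")
            manifest["stages"][stage] = {"status": "ok"}

            stage = "differential"
            a, b = tables
            shared = sorted(set(a["gene"]) & set(b["gene"]))
            rep_a = [c for c in a.columns if c.startswith("rep")]
            rep_b = [c for c in b.columns if c.startswith("rep")]
            va = a.set_index("gene").loc[shared, rep_a].to_numpy()
            vb = b.set_index("gene").loc[shared, rep_b].to_numpy()
            deg_res = differential.rank_product(va, vb, n_perm=cfg.n_perm,
                                                seed=cfg.seed, ids=shared)
            deg_res.to_csv(out / "rank_product_expression.tsv", sep="\t",
                           index=False, float_format="%.6g")
            degs = differential.identify_significant(deg_res, cfg.q_threshold)["union"]

            piv = est_frame[~est_frame["no_growth"]].pivot_table(
                index="strain", columns=["medium", "replicate"], values="mu"
            )
            g_shared = [s for s in piv.index if not piv.loc[s].isna().any()]
            ga = piv.loc[g_shared, cfg.media[0]].to_numpy()
            gb = piv.loc[g_shared, cfg.media[1]].to_numpy()
            dgg_res = differential.rank_product(ga, gb, n_perm=cfg.n_perm,
                                                seed=cfg.seed + 1, ids=g_shared)
            dgg_res.to_csv(out / "rank_product_growth.tsv", sep="\t",
                           index=False, float_format="%.6g")
            dggs = differential.identify_significant(dgg_res, cfg.q_threshold)["union"]
            venn = differential.deg_dgg_overlap(degs, dggs, set(shared), set(g_shared))
            venn["table"].to_csv(out / "deg_dgg_overlap.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "status": "ok", "n_deg": len(degs), "n_dgg": len(dggs),
                "overlap": venn["both"],
            }

            stage = "association"
            expr_all = pd.concat(tables, ignore_index=True)
            join = association.join_growth_expression(rate_table, expr_all, ann)
            join.to_csv(out / "growth_expression_join.tsv", sep="\t", index=False,
                        float_format="%.6g")
            assoc = {}
            for medium in cfg.media:
                rho, p = association.spearman_growth_expression(join, medium)
                rand = association.randomization_test(
                    join, medium, n_shuffles=cfg.n_shuffles, seed=cfg.seed
                )
                assoc[medium] = {
                    "rho": rho, "p": p,
                    "randomization_p": rand.empirical_p,
                }
            manifest["stages"][stage] = {"status": "ok", **assoc}
        else:
            for skipped in ("normalization", "differential", "association"):
                manifest["stages"][skipped] = {"status": "skipped",
                                               "reason": "no expression tables"}

        stage = "periodicity"
        peri = {}
        ess_density = periodicity.positional_signal(
            ann[ann["essential"]], None, mode="density", genome_length_kb=L,
            window_kb=cfg.window_kb, bin_step_kb=cfg.bin_step_kb,
        )
        for medium in cfg.media:
            rates = rate_table[rate_table["medium"] == medium].set_index("strain")["mu_mean"]
            sig = periodicity.positional_signal(
                ann, rates, mode="essential_zero", genome_length_kb=L,
                window_kb=cfg.window_kb, bin_step_kb=cfg.bin_step_kb,
            )
            dom = periodicity.dominant_period(sig, exclude_k1=cfg.exclude_k1)
            dom.to_frame().to_csv(out / f"periodogram_growth_{medium}.tsv",
                                  sep="\t", index=False, float_format="%.6g")
            r, rp = periodicity.essential_density_correlation(sig, ess_density)
            peri[medium] = {
                "dominant_k": dom.dominant_k,
                "wavelength_kb": dom.dominant_wavelength_kb,
                "g": dom.g, "g_pvalue": dom.g_pvalue,
                "essential_density_r": r, "essential_density_p": rp,
            }
        manifest["stages"][stage] = {"status": "ok", **peri}
    except KogrowthError as exc:
        manifest["stages"][stage] = {"status": "error", "message": str(exc)}
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
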