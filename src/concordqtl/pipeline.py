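"""End-to-end orchestration: simulate -> deregress -> map -> regions ->
status -> concordance -> LD diagnostics.

Every stage persists its result as TSV (or VCF) in the output directory,
so any downstream stage can be rerun in isolation from the files alone.
All randomness is derived from the single global seed via stable
stage-name hashing; two runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from . import deregression, ld, regions as regions_mod, simulate as sim
from .bayesc import BayesCConfig, run_bayesc
from .config import load_config, stage_seed
from .datatypes import STATUS_HET, STATUS_HOM, STATUS_UNKNOWN
from .io_formats import (
    read_annotation_table,
    read_ebv_table,
    read_phased_vcf,
    read_sequence_vcf,
    write_report,
)
from .status import infer_status

log = logging.getLogger("concordqtl")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: dict | str) -> dict:
    """Run all stages from one config; returns the run report (also
    written as ``report.json`` in the output directory)."""
    cfg = load_config(config) if isinstance(config, str) else load_config(None, config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "stages": {}}

    # ---- inputs: simulate or load --------------------------------------
    truth = None
    sim_cfg = None
    try:
        if "simulate" in cfg:
            sim_cfg = sim.SimulationConfig(
                **{**cfg["simulate"], "seed": stage_seed(seed, "simulate")}
            )
            pop = sim.simulate_population(sim_cfg)
            paths = {
                "panel_vcf": str(outdir / "panel.vcf"),
                "sequence_vcf": str(outdir / "sequence.vcf"),
                "ebv_tsv": str(outdir / "ebv.tsv"),
                "pedigree_tsv": str(outdir / "pedigree.tsv"),
                "truth_tsv": str(outdir / "truth.tsv"),
            }
            sim.emit_vcfs(
                pop,
                paths["panel_vcf"],
                paths["sequence_vcf"],
                paths["ebv_tsv"],
                paths["pedigree_tsv"],
                paths["truth_tsv"],
            )
            truth = pop.truth
            sequenced = pop.sequenced_ids
            annotation_tsv = None
            report["stages"]["simulate"] = {
                "n_animals": sim_cfg.n_animals,
                "n_sequenced": sim_cfg.n_sequenced,
                "n_seq_variants": sim_cfg.n_seq_variants,
                "qtl_variant_index": sim_cfg.qtl_variant_index,
            }
        else:
            paths = dict(cfg["inputs"])
            for key in ("panel_vcf", "ebv_tsv", "sequence_vcf"):
                if not paths.get(key):
                    raise ValueError(f"inputs.{key} is required without simulate")
            sequenced = None
            annotation_tsv = paths.get("annotation_tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc

    # ---- deregression ---------------------------------------------------
    try:
        ebv = read_ebv_table(paths["ebv_tsv"])
        dereg = deregression.deregress_table(
            ebv, h2=cfg["deregression"]["h2"], form=cfg["deregression"]["weight_form"]
        )
        write_report(dereg, outdir / "deregressed.tsv")
        report["stages"]["deregression"] = {"n_records": int(len(dereg))}
    except Exception as exc:  # noqa: BLE001
        raise StageError("deregression", exc) from exc

    # ---- mapping --------------------------------------------------------
    try:
        panel, haps = read_phased_vcf(paths["panel_vcf"])
        dereg = dereg.set_index("animal_id").loc[
            [str(a) for a in haps.animal_ids]
        ].reset_index()
        fhaps, kept = regions_mod.maf_filter(haps, cfg["regions"]["maf_min"])
        bc = cfg["bayesc"]
        bconf = BayesCConfig(
            pi=bc["pi"],
            nu=bc["nu"],
            n_iter=bc["n_iter"],
            burn_in=bc["burn_in"],
            thin=bc["thin"],
            sigma2_a_prior=bc["sigma2_a_prior"],
            sigma2_e_prior=bc["sigma2_e_prior"],
            sigma2_u_prior=bc["sigma2_u_prior"],
            polygenic_enabled=bc["polygenic_enabled"],
            use_weights=bc["use_weights"],
            seed=stage_seed(seed, "bayesc"),
        )
        posterior = run_bayesc(
            dereg["y"].to_numpy(),
            fhaps,
            bconf,
            weights=dereg["w"].to_numpy(),
        )
        post_df = posterior.to_frame(fhaps.panel)
        write_report(post_df, outdir / "posterior.tsv")
        report["stages"]["bayesc"] = {
            "n_markers": int(fhaps.panel.n_markers),
            "n_retained": int(posterior.n_retained),
            "sigma2_a_mean": float(posterior.sigma2_a_mean),
            "sigma2_e_mean": float(posterior.sigma2_e_mean),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("bayesc", exc) from exc

    # ---- region selection ----------------------------------------------
    try:
        rcfg = cfg["regions"]
        windows = regions_mod.window_sums(fhaps.panel, posterior.p, L=rcfg["L"])
        if rcfg.get("mode") == "disjoint":
            windows = windows[windows["start_idx"] % rcfg["L"] == 0].reset_index(
                drop=True
            )
        selected = regions_mod.select_regions(windows, fhaps.panel, K=rcfg["K"])
        regions_mod.attach_subintervals(selected, posterior.p)
        rtab = regions_mod.regions_table(selected)
        write_report(rtab, outdir / "regions.tsv")
        report["stages"]["regions"] = {
            "n_windows": int(len(windows)),
            "n_selected": int(len(selected)),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("regions", exc) from exc

    # ---- status inference ------------------------------------------------
    try:
        scfg = cfg["status"]
        status_frames = []
        status_counts = []
        for reg in selected:
            calls, diag = infer_status(
                reg,
                posterior.a_hat,
                fhaps,
                interval_mode=scfg["interval"],
                seed=stage_seed(seed, f"status:{reg.rank}"),
                restarts=scfg["restarts"],
            )
            calls.insert(0, "region", reg.rank)
            status_frames.append(calls)
            status_counts.append(
                {
                    "region": reg.rank,
                    "k": diag["k"],
                    "hom": int((calls["status"] == STATUS_HOM).sum()),
                    "het": int((calls["status"] == STATUS_HET).sum()),
                    "unknown": int((calls["status"] == STATUS_UNKNOWN).sum()),
                }
            )
        status_all = pd.concat(status_frames, ignore_index=True)
        write_report(status_all, outdir / "status.tsv")
        report["stages"]["status"] = {"regions": status_counts}
    except Exception as exc:  # noqa: BLE001
        raise StageError("status", exc) from exc

    # ---- concordance ------------------------------------------------------
    try:
        ccfg = cfg["concordance"]
        seq = read_sequence_vcf(paths["sequence_vcf"], sample_subset=sequenced)
        annotation = (
            read_annotation_table(annotation_tsv) if annotation_tsv else None
        )
        conc_blocks = []
        conc_report = []
        sweeps = []
        for reg in selected:
            reg_seq = seq.subset_region(reg.chrom, reg.start_bp, reg.end_bp)
            if reg_seq.n_variants == 0:
                conc_report.append(
                    {"region": reg.rank, "n_poly": 0, "n_concordant": 0}
                )
                continue
            calls = status_all[status_all["region"] == reg.rank]
            if not calls["status"].isin([STATUS_HOM, STATUS_HET]).any():
                # nothing to compare against (e.g. degenerate status stage)
                conc_report.append(
                    {"region": reg.rank, "n_poly": int(reg_seq.n_variants),
                     "n_concordant": 0}
                )
                continue
            table = conc.concordance_table(reg_seq, calls, gq_min=ccfg["gq_min"])
            filt = conc.concordance_filter(
                table,
                n_poly=reg_seq.n_variants,
                fraction_min=ccfg["fraction_min"],
                min_het=ccfg["min_het"],
                min_hom=ccfg["min_hom"],
            )
            filt = conc.annotate_join(filt, annotation)
            filt.insert(0, "region", reg.rank)
            conc_blocks.append(filt)
            conc_report.append(
                {
                    "region": reg.rank,
                    "n_poly": int(reg_seq.n_variants),
                    "n_concordant": int(filt["concordant"].sum()),
                }
            )
            if ccfg.get("sweep", True):
                sw = conc.sweep_tolerance(
                    table,
                    n_poly=reg_seq.n_variants,
                    min_het=ccfg["min_het"],
                    min_hom=ccfg["min_hom"],
                )
                sw.insert(0, "region", reg.rank)
                sweeps.append(sw)
        conc_all = (
            pd.concat(conc_blocks, ignore_index=True) if conc_blocks else pd.DataFrame()
        )
        write_report(conc_all, outdir / "concordance.tsv")
        if sweeps:
            write_report(pd.concat(sweeps, ignore_index=True), outdir / "sweep.tsv")
        report["stages"]["concordance"] = {"regions": conc_report}
    except Exception as exc:  # noqa: BLE001
        raise StageError("concordance", exc) from exc

    # ---- LD diagnostics ----------------------------------------------------
    if cfg["ld"]["enabled"] and selected:
        try:
            top = selected[0]
            ld_tab = ld.region_ld(fhaps, top)
            write_report(ld_tab, outdir / "ld.tsv")
            report["stages"]["ld"] = {
                "region": top.rank,
                "n_pairs": int(len(ld_tab)),
                "mean_abs_dprime": float(np.nanmean(np.abs(ld_tab["Dprime"]))),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("ld", exc) from exc

    # ---- truth evaluation (simulation only) --------------------------------
    if truth is not None and sim_cfg is not None:
        qtl_pos = int(
            pop.variant_panel.table["pos"].iloc[sim_cfg.qtl_variant_index]
        )
        block: dict = {"qtl_pos": qtl_pos}
        if sim_cfg.qtl_effect == 0:
            block["note"] = "no signal planted"
        hit = next(
            (
                r
                for r in selected
                if r.chrom == sim_cfg.chrom and r.start_bp <= qtl_pos <= r.end_bp
            ),
            None,
        )
        block["qtl_in_selected_region"] = hit is not None
        if hit is not None and not conc_all.empty:
            sub = conc_all[conc_all["region"] == hit.rank]
            row = sub[sub["pos"] == qtl_pos]
            block["causative_retained"] = bool(
                len(row) and bool(row["concordant"].iloc[0])
            )
            n_poly = int(
                next(
                    r["n_poly"]
                    for r in conc_report
                    if r["region"] == hit.rank
                )
            )
            block["candidate_fraction"] = (
                float(sub["concordant"].sum() / n_poly) if n_poly else None
            )
            # status accuracy among called, truth-matched animals
            calls = status_all[status_all["region"] == hit.rank].merge(
                truth, on="animal_id"
            )
            called = calls[calls["status_x"].isin([STATUS_HOM, STATUS_HET])]
            block["status_accuracy"] = (
                float((called["status_x"] == called["status_y"]).mean())
                if len(called)
                else None
            )
        report["truth_evaluation"] = block

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", report_path)
    return report
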