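"""End-to-end orchestration: simulate -> genotype -> quantify ->
signatures -> clinical, with per-stage seeds, checksummed outputs and a
JSON run report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import genotyping as gt
from . import junctions as jx
from .signatures import (
    build_catalog_96,
    match_to_reference,
    select_signature_number,
    summarize_categories,
    tetranucleotide_attribution,
    toy_reference_catalog,
)
from .sim import SimConfig, simulate_cohort, write_fixture_bundle

log = logging.getLogger("apobec3kit.pipeline")

_TOP_KEYS = {"outdir", "seed", "simulate", "genotyping", "quantify", "signatures", "verbosity"}
_QUANT_KEYS = {"max_mismatch", "seed_len", "min_overhang", "min_reads"}
_SIG_KEYS = {"k_range", "n_bootstraps", "n_restarts", "stability_cutoff"}
_GENO_KEYS = {"max_iter", "tol", "posterior_threshold"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def validate_config(config: dict) -> dict:
    """Reject unknown keys anywhere in the config tree."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    for block, allowed in (
        ("simulate", sim_fields),
        ("quantify", _QUANT_KEYS),
        ("signatures", _SIG_KEYS),
        ("genotyping", _GENO_KEYS),
    ):
        extra = set(config.get(block, {})) - allowed
        if extra:
            raise ValueError(f"unknown keys in {block!r} block: {sorted(extra)}")
    if "outdir" not in config:
        raise ValueError("config needs an 'outdir'")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage child seed (below 2^31)."""
    import zlib

    return (int(root_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


def run_pipeline(config: dict) -> dict:
    """Run every stage in dependency order and return the run report.

    Any stage failure raises :class:`PipelineError` naming the stage;
    outputs already written by earlier stages are left intact.
    """
    cfg = validate_config(dict(config))
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg.get("seed", 0))
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    report: dict = {"seed": root_seed, "stages": {}, "headline": {}, "checksums": {}}
    t_all = time.time()

    def run_stage(name, fn):
        t0 = time.time()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            _finalise(report, out, t_all)
            raise PipelineError(name, str(exc)) from exc
        report["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        log.info("stage %s: done (%.1fs)", name, time.time() - t0)

    state: dict = {}

    def s_simulate():
        sim_kwargs = dict(cfg.get("simulate", {}))
        sim_kwargs["seed"] = stage_seed(root_seed, "simulate")
        state["cohort"] = simulate_cohort(SimConfig(**sim_kwargs))
        write_fixture_bundle(state["cohort"], out / "fixture")

    def s_genotype():
        cohort = state["cohort"]
        ratios = gt.compute_depth_ratios(cohort.depth)
        calls, summary = gt.em_genotype_cohort(ratios, **cfg.get("genotyping", {}))
        calls.to_csv(out / "genotype_calls.tsv", sep="\t", index=False)
        with open(out / "genotype_fit.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        state["calls"] = calls
        truth = cohort.genotypes
        conc = float(np.mean(calls.call.to_numpy() == truth))
        report["headline"]["genotype_concordance"] = conc
        report["headline"]["allele_freq_estimate"] = summary["allele_freq"]
        report["headline"]["genotype_counts"] = {
            lab: int((calls.label == lab).sum()) for lab in gt.GENOTYPE_LABELS.values()
        }

    def s_quantify():
        cohort = state["cohort"]
        qcfg = cfg.get("quantify", {})
        rl = cohort.config.read_length
        tx_index = jx.ReferenceIndex(
            cohort.locus.transcript_seqs, qcfg.get("seed_len", 31)
        )
        jdb = jx.junction_db_from_locus(cohort.locus, rl)
        fusion_refs = dict(cohort.locus.contigs["nondeleted"])
        fusion_refs.update(
            {f"del|{k}": v for k, v in cohort.locus.contigs["deleted"].items()}
        )
        fusion_refs.update(jdb.sequences)
        fusion_index = jx.ReferenceIndex(fusion_refs, qcfg.get("seed_len", 31))
        call_by_sample = dict(zip(state["calls"]["sample"], state["calls"]["call"]))
        tpm_rows, fusion_rows = [], []
        for (sid, tissue), lib in sorted(cohort.reads.items()):
            c = int(call_by_sample.get(sid, 0))
            res = jx.quantify_library(
                lib,
                cohort.locus.transcript_seqs,
                genotype=c,
                read_length=rl,
                max_mismatch=qcfg.get("max_mismatch", 2),
                index=tx_index,
            )
            row = {"sample": sid, "tissue": tissue, **res.tpm.to_dict()}
            row["A3A_gene"] = res.gene_level_a3a_tpm
            tpm_rows.append(row)
            fa = jx.assign_reads(lib, fusion_index, max_mismatch=qcfg.get("max_mismatch", 2))
            det = jx.detect_fusion_junction_reads(
                fa,
                jdb,
                min_overhang=qcfg.get("min_overhang", 8),
                min_reads=qcfg.get("min_reads", 2),
            )
            fusion_rows.append(
                {"sample": sid, "tissue": tissue, "fusion_reads": det["count"],
                 "fusion_present": det["present"]}
            )
        state["tpm"] = pd.DataFrame(tpm_rows)
        state["fusion"] = pd.DataFrame(fusion_rows)
        state["tpm"].to_csv(out / "tpm.tsv", sep="\t", index=False)
        state["fusion"].to_csv(out / "fusion_counts.tsv", sep="\t", index=False)
        report["headline"]["fusion_positive_tumors"] = int(
            state["fusion"].query("tissue == 'tumor'").fusion_present.sum()
        )

    def s_signatures():
        cohort = state["cohort"]
        scfg = cfg.get("signatures", {})
        catalog, cat_report = build_catalog_96(cohort.mutations, cohort.context_genome)
        catalog.to_csv(out / "catalog96.tsv", sep="\t")
        sel = select_signature_number(
            catalog,
            scfg.get("k_range", (1, 2, 3, 4)),
            stability_cutoff=scfg.get("stability_cutoff", 0.85),
            n_bootstraps=scfg.get("n_bootstraps", 30),
            n_restarts=scfg.get("n_restarts", 3),
            seed=stage_seed(root_seed, "signatures"),
        )
        best = sel.best
        best.signatures.to_csv(out / "signatures.tsv", sep="\t")
        best.exposures.to_csv(out / "exposures.tsv", sep="\t")
        matches = match_to_reference(best.signatures, toy_reference_catalog())
        per_sample, cohort_frac = summarize_categories(matches, best.exposures)
        per_sample.to_csv(out / "category_per_sample.tsv", sep="\t")
        attribution = tetranucleotide_attribution(cohort.mutations, cohort.context_genome)
        attribution.counts.to_csv(out / "tetranucleotide_counts.tsv", sep="\t")
        with open(out / "signature_summary.json", "w") as fh:
            json.dump(
                {
                    "chosen_k": sel.chosen_k,
                    "below_cutoff": sel.below_cutoff,
                    "diagnostics": sel.diagnostics.to_dict("records"),
                    "matches": matches.drop(columns=[]).to_dict("records"),
                    "category_fractions": cohort_frac.to_dict(),
                    "ytca_rtca": list(attribution.pooled_ytca_rtca),
                    "wilcoxon_p": attribution.wilcoxon_p,
                    "catalog_report": {k: v for k, v in cat_report.items() if k != "rejected_rows"},
                },
                fh,
                indent=2,
            )
        report["headline"]["chosen_k"] = sel.chosen_k
        report["headline"]["category_fractions"] = cohort_frac.round(4).to_dict()
        y, r = attribution.pooled_ytca_rtca
        report["headline"]["ytca_fraction"] = y / max(y + r, 1)

    def s_clinical():
        cohort = state["cohort"]
        tum = state["tpm"].query("tissue == 'tumor'").set_index("sample")
        a3a = tum["A3A_gene"].reindex(cohort.sample_ids).fillna(0.0)
        groups, _ = clin.median_split(a3a.to_numpy())
        table = cohort.clinical.copy()
        table["expression_group"] = groups
        table["group_high"] = (table.expression_group == "high").astype(int)
        lr = clin.logrank_test(table.time, table.event, table.expression_group)
        cox = clin.cox_fit(table, ["group_high", "age_group", "sex"])
        km_rows = []
        for lab, sub in table.groupby("expression_group"):
            curve = clin.km_estimate(sub.time, sub.event)
            for t, s in zip(curve.event_times, curve.survival):
                km_rows.append({"group": lab, "time": t, "survival": s})
        pd.DataFrame(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        xtab = pd.crosstab(table.sex, table.expression_group).to_numpy()
        xres = clin.crosstab_report(xtab) if xtab.shape == (2, 2) else None
        table.to_csv(out / "clinical_annotated.tsv", sep="\t", index=False)
        with open(out / "survival_summary.json", "w") as fh:
            json.dump(
                {
                    "logrank_p": lr.p,
                    "logrank_statistic": lr.statistic,
                    "cox": cox.summary().to_dict("index"),
                    "sex_crosstab": xres,
                },
                fh,
                indent=2,
            )
        report["headline"]["logrank_p"] = lr.p
        report["headline"]["cox_hr_high_expression"] = float(cox.hazard_ratio[0])

    run_stage("simulate", s_simulate)
    run_stage("genotype", s_genotype)
    run_stage("quantify", s_quantify)
    run_stage("signatures", s_signatures)
    run_stage("clinical", s_clinical)
    _finalise(report, out, t_all)
    return report


def _finalise(report: dict, out: Path, t_start: float):
    report["checksums"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("run_report.json", "config_echo.yaml")
    }
    report["total_seconds"] = round(time.time() - t_start, 2)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# call-set concordance


def concordance_report(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    panel_regions: pd.DataFrame,
) -> dict:
    """Fraction of panel-region calls in ``calls_a`` confirmed in ``calls_b``.

    Call sets are keyed by (sample, chrom, pos, ref, alt) with 1-based
    positions; ``panel_regions`` is BED-like (chrom, start, end; 0-based
    half-open).  Malformed records are rejected and counted.
    """

    def keys(df, counter):
        out = set()
        for r in df.itertuples(index=False):
            try:
                key = (str(r.sample), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
                if key[3] in ("", "nan") or key[4] in ("", "nan"):
                    raise ValueError
                out.add(key)
            except (ValueError, TypeError, AttributeError):
                counter["rejected"] += 1
        return out

    counter = {"rejected": 0}
    a, b = keys(calls_a, counter), keys(calls_b, counter)
    in_panel = set()
    for key in a:
        _, chrom, pos, _, _ = key
        hit = (
            (panel_regions.chrom == chrom)
            & (panel_regions.start <= pos - 1)
            & (pos - 1 < panel_regions.end)
        ).any()
        if hit:
            in_panel.add(key)
    confirmed = in_panel & b
    per_sample = {}
    for s in sorted({k[0] for k in in_panel}):
        denom = [k for k in in_panel if k[0] == s]
        num = [k for k in denom if k in b]
        per_sample[s] = len(num) / len(denom)
    overall = len(confirmed) / len(in_panel) if in_panel else float("nan")
    return {
        "overall": overall,
        "per_sample": per_sample,
        "n_in_panel": len(in_panel),
        "n_confirmed": len(confirmed),
        "rejected_records": counter["rejected"],
    }
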