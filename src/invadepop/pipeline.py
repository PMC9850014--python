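"""End-to-end pipeline: filter -> diversity -> Ne -> structure -> ABC ->
spatial, driven by one TOML config with per-stage seeds.

Each stage writes its outputs under the run directory and records what
it did (inputs, outputs, counts, seed) in ``manifest.json``.  Re-running
with the same config resumes: completed stages whose config section is
unchanged are skipped.  A missing distance matrix skips the spatial
stages with an explicit notice; everything else still runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc_rf, diversity, genotype_io, ne_ld, spatial, structure
from .genotype_io import InvadepopError

logger = logging.getLogger("invadepop")

DEFAULTS = {
    "filter": {
        "locus_missingness": 0.30,
        "individual_missingness": 0.30,
        "min_mac": 2,
        "h_max": 0.55,
        "d_max": 7.0,
    },
    "diversity": {"n_perm": 5000, "n_bootstrap": 1000, "seed": 1},
    "ne": {"pcrit": [0.0, 0.1, 0.2, 0.5]},
    "structure": {"k_max": 10, "seed": 2},
    "abc": {
        "enabled": True,
        "n_per_scenario": 500,
        "n_loci": 300,
        "n_trees": 1000,
        "paper_scale": False,
        "seed": 3,
    },
    "spatial": {
        "class_start": 10.0,
        "class_end": 300.0,
        "class_step": 10.0,
        "n_perm": 999,
        "radius_km": 220.0,
        "min_n": 20,
        "seed": 4,
    },
}


def load_config(path: str) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    merged = {k: dict(v) for k, v in DEFAULTS.items()}
    for section, values in cfg.items():
        if section in merged and isinstance(values, dict):
            merged[section].update(values)
        else:
            merged[section] = values
    return merged


def _section_hash(cfg: dict, section: str) -> str:
    blob = json.dumps(cfg.get(section, {}), sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())

    def done(self, stage: str, h: str) -> bool:
        info = self.data["stages"].get(stage)
        return bool(info and info.get("complete") and info.get("config_hash") == h)

    def record(self, stage: str, h: str, **info) -> None:
        self.data["stages"][stage] = {"complete": True, "config_hash": h, **info}
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(config: dict | str, out_dir: str) -> Path:
    """Run all stages in dependency order; returns the run directory."""
    if isinstance(config, str):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    inputs = config.get("inputs", {})
    if "vcf" not in inputs or "metadata" not in inputs:
        raise InvadepopError("config must name inputs.vcf and inputs.metadata")
    meta = pd.read_csv(inputs["metadata"], sep="\t")

    # ---- filter ---------------------------------------------------------
    h = _section_hash(config, "filter")
    filtered_vcf = out / "filtered.vcf"
    if manifest.done("filter", h) and filtered_vcf.exists():
        g = genotype_io.read_vcf(str(filtered_vcf))
    else:
        fc = config["filter"]
        raw = genotype_io.read_vcf(inputs["vcf"])
        log = genotype_io.FilterLog()
        g = genotype_io.filter_cascade(
            raw,
            locus_threshold=fc["locus_missingness"],
            individual_threshold=fc["individual_missingness"],
            min_mac=fc["min_mac"],
            h_max=fc["h_max"],
            d_max=fc["d_max"],
            log=log,
        )
        genotype_io.write_vcf(g, str(filtered_vcf))
        per_locus, per_ind = genotype_io.qc_report(raw)
        per_locus.to_csv(out / "qc_loci.tsv", sep="\t", index=False)
        per_ind.to_csv(out / "qc_individuals.tsv", sep="\t", index=False)
        manifest.record(
            "filter", h,
            loci_in=raw.n_loci, loci_out=g.n_loci,
            individuals_in=raw.n_samples, individuals_out=g.n_samples,
            removed_loci=len(log.removed_loci),
            removed_individuals=len(log.removed_samples),
        )
    meta = meta[meta["sample_id"].isin(g.sample_ids)].reset_index(drop=True)
    meta = meta.set_index("sample_id").loc[g.sample_ids].reset_index()
    era = meta["era"].to_numpy()

    # ---- diversity ------------------------------------------------------
    h = _section_hash(config, "diversity")
    if not manifest.done("diversity", h):
        dc = config["diversity"]
        rng = np.random.default_rng(dc["seed"])
        tables = diversity.diversity_by_group(g, era)
        rows = []
        for lab, t in tables.items():
            t.per_locus.assign(group=lab).to_csv(
                out / f"diversity_{lab}.tsv", sep="\t", index=False
            )
            rows.append({"group": lab, "Ho": t.mean_ho, "Hs": t.mean_hs,
                         "Fis": t.mean_fis})
        summary = {"groups": rows}
        mlh_v = diversity.mlh(g)
        ir_v = diversity.ir(g)
        pd.DataFrame(
            {"sample_id": g.sample_ids, "MLH": mlh_v, "IR": ir_v, "era": era}
        ).to_csv(out / "individual_diversity.tsv", sep="\t", index=False)
        if len(set(era)) == 2:
            for name, vals in (("MLH", mlh_v), ("IR", ir_v)):
                tr = diversity.permutation_mean_diff(
                    vals, era, n_perm=dc["n_perm"], seed=rng
                )
                summary[f"perm_{name}"] = {"stat": tr.statistic, "p": tr.p_value}
            labs = sorted(set(era))
            sub = {lab: g.take_samples(np.flatnonzero(era == lab)) for lab in labs}
            common = [t.per_locus for t in
                      (diversity.ho_hs_fis(sub[labs[0]]), diversity.ho_hs_fis(sub[labs[1]]))]
            merged = common[0].merge(common[1], on="locus_id", suffixes=("_a", "_b"))
            for col in ("Ho", "Hs"):
                try:
                    tr = diversity.paired_wilcoxon_by_locus(
                        merged[f"{col}_a"].to_numpy(), merged[f"{col}_b"].to_numpy()
                    )
                    summary[f"wilcoxon_{col}"] = {"stat": tr.statistic, "p": tr.p_value}
                except InvadepopError as e:
                    summary[f"wilcoxon_{col}"] = {"error": str(e)}
            fst = diversity.weir_cockerham_fst(
                g, era, n_bootstrap=dc["n_bootstrap"], seed=rng
            )
            summary["fst"] = fst
        (out / "diversity_summary.json").write_text(json.dumps(summary, indent=2))
        manifest.record("diversity", h, n_loci=g.n_loci)

    # ---- Ne -------------------------------------------------------------
    h = _section_hash(config, "ne")
    if not manifest.done("ne", h):
        idx_c = np.flatnonzero(era == "contemporary")
        target = g.take_samples(idx_c) if len(idx_c) >= 10 else g
        res = []
        rows = []
        for pc in config["ne"]["pcrit"]:
            try:
                r = ne_ld.ne_ld_estimate(target, (pc,))[0]
                res.append(r)
                rows.append(asdict(r))
            except InvadepopError as e:
                rows.append({"pcrit": pc, "error": str(e)})
        pd.DataFrame(rows).to_csv(out / "ne_ld.tsv", sep="\t", index=False)
        manifest.record(
            "ne", h, spread=ne_ld.pcrit_spread(res) if res else float("nan")
        )

    # ---- structure ------------------------------------------------------
    h = _section_hash(config, "structure")
    if not manifest.done("structure", h):
        sc = config["structure"]
        p = structure.pca(g)
        scan = structure.kmeans_bic_scan(p.scores, k_max=sc["k_max"], seed=sc["seed"])
        pd.DataFrame(
            {"K": np.arange(1, len(scan.bic) + 1), "BIC": scan.bic}
        ).to_csv(out / "kmeans_bic.tsv", sep="\t", index=False)
        pd.DataFrame(
            p.scores[:, :10],
            columns=[f"PC{i + 1}" for i in range(min(10, p.scores.shape[1]))],
        ).assign(sample_id=g.sample_ids).to_csv(
            out / "pca_scores.tsv", sep="\t", index=False
        )
        info = {
            "best_k_min": scan.best_k_min,
            "best_k_diffngroup": scan.best_k_diffngroup,
            "pc_variance": list(map(float, p.proportion_variance[:10])),
        }
        (out / "structure_summary.json").write_text(json.dumps(info, indent=2))
        manifest.record("structure", h, **info)

    # ---- ABC ------------------------------------------------------------
    h = _section_hash(config, "abc")
    ac = config["abc"]
    if ac.get("enabled", True) and not manifest.done("abc", h):
        n_per = 5000 if ac.get("paper_scale") else ac["n_per_scenario"]
        n_loci = 1898 if ac.get("paper_scale") else ac["n_loci"]
        n_hist = int((era == "historical").sum()) or 8
        n_cont = int((era == "contemporary").sum())
        ref = abc_rf.build_reference_table(
            n_per_scenario=n_per, n_loci=n_loci,
            n_historical=n_hist, n_contemporary=n_cont, seed=ac["seed"],
        )
        from .simulate import SimulatedDataset

        obs = abc_rf.summarize(SimulatedDataset(g, meta))
        out_abc = {}
        for level in ("group", "scenario"):
            r = abc_rf.scenario_choice(
                ref, obs, level, n_trees=ac["n_trees"], seed=ac["seed"]
            )
            out_abc[level] = {
                "votes": r.votes,
                "selected": r.selected,
                "posterior_probability": r.posterior_probability,
                "prior_error_rate": r.prior_error_rate,
            }
        sel = out_abc["scenario"]["selected"]
        ref_sel = ref.restrict(sel)
        if ref_sel.n_rows >= 500:
            est = abc_rf.estimate_parameters(
                ref_sel, obs, ("Nancestral", "Nbottleneck", "td"),
                n_trees=ac["n_trees"], seed=ac["seed"],
            )
            out_abc["parameters"] = [asdict(e) for e in est]
        (out / "abc_results.json").write_text(json.dumps(out_abc, indent=2, default=str))
        manifest.record("abc", h, n_rows=ref.n_rows)

    # ---- spatial --------------------------------------------------------
    h = _section_hash(config, "spatial")
    if not manifest.done("spatial", h):
        if "distances" not in inputs:
            logger.warning("no distance matrix configured: spatial stages skipped")
            manifest.record("spatial", h, skipped="no distance matrix")
        else:
            sp = config["spatial"]
            d = spatial.load_distances(inputs["distances"], sample_ids=g.sample_ids)
            gd = spatial.proportion_shared_allele_distance(g)
            cg = spatial.mantel_correlogram(
                gd, d, sp["class_start"], sp["class_end"], sp["class_step"],
                n_perm=sp["n_perm"], seed=sp["seed"],
            )
            cg.to_frame().to_csv(out / "correlogram.tsv", sep="\t", index=False)
            nd = spatial.neighborhood_diversity(
                g, d, radius_km=sp["radius_km"], min_n=sp["min_n"]
            )
            nd.to_csv(out / "neighborhood_diversity.tsv", sep="\t", index=False)
            models = {}
            mlh_v = diversity.mlh(g)
            ir_v = diversity.ir(g)
            for name, vals in (("MLH", mlh_v), ("IR", ir_v)):
                try:
                    m = spatial.decay_regression(vals, meta, response_name=name)
                    models[name] = asdict(m)
                except InvadepopError as e:
                    models[name] = {"error": str(e)}
            summary = {
                "neighbourhood_size_km": cg.neighbourhood_size_km,
                "first_nonsignificant_km": cg.first_nonsignificant_km,
                "eradication_radius_km": cg.eradication_radius_km,
                "decay_models": models,
            }
            (out / "spatial_summary.json").write_text(
                json.dumps(summary, indent=2, default=str)
            )
            manifest.record("spatial", h, neighbourhood=cg.neighbourhood_size_km)
    return out
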