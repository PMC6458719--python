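"""End-to-end orchestration from a single YAML configuration.

Stages run in dependency order: synthetic-genome generation (or loading of
user files), lncTU atlas assembly, count simulation/loading, differential
expression, co-expression clustering, positional motif discovery,
regulatory context (chromatin states, NATs, TFBSs), and ploidy. Each
stage's outputs are written under the configured output directory and
checksummed into a manifest; deterministic stages reproduce identical
checksums for identical configs. One global seed is fanned out per stage
through numpy SeedSequence spawn keys so any stage can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import clustering, context, diffexpr, io, plm, ploidy, simulate
from .intervals import LncTU

# Stage parameter defaults follow the study design: DE alpha 0.05, K sweep
# 10..40, k-mers 4..11, 1000 shuffles, 3 kb up / 1 kb down TFBS window,
# term-enrichment FDR 0.01 with >= 10 mapping entries.
DEFAULTS: Dict[str, dict] = {
    "de": {"alpha": 0.05},
    "clustering": {"k_min": 10, "k_max": 40, "n_restarts": 10,
                   "theta": 0.05, "theta_high": 0.15},
    "motifs": {"k_min": 4, "k_max": 11, "alpha": 0.05},
    "context": {"n_shuffles": 1000, "metric": "count",
                "window_up": 3000, "window_down": 1000},
    "enrichment": {"fdr": 0.01, "min_entries": 10},
}

# Planted relative expression profiles over (T0, T2, T3, T5): a transient
# cluster, a rising cluster, a falling cluster, and a flat null cluster.
DEFAULT_PROFILES = [
    [50.0, 200.0, 200.0, 50.0],
    [50.0, 100.0, 200.0, 400.0],
    [400.0, 200.0, 100.0, 50.0],
    [100.0, 100.0, 100.0, 100.0],
]

DEFAULT_SYNTHETIC = {
    "n_chrom": 2,
    "chrom_len": 300_000,
    "n_genes": 120,
    "lnc": {"n_datasets": 3, "n_chains": 60, "redundancy": 0.6,
            "strand_na_fraction": 0.2, "antisense_fraction": 0.3},
    "counts": {"dispersion": 0.1, "libsize_range": [0.8, 1.2],
               "base_mean": 100.0},
    "profiles": DEFAULT_PROFILES,
    "motif_plants": [
        {"cluster": 0, "motif": "AAACCCTA", "fraction": 0.6, "window": "target"},
    ],
    "state_bias": {"CS4": 5.0},
    # class percentages chosen so the noiseless EIs match the reported
    # leaves-3/4 endpoints: 1.95 without transfer, 2.35 after transfer
    "ploidy": {
        "profiles": {"15dwt": [10.0, 25.0, 30.0, 30.0, 5.0],
                     "15dat": [8.0, 18.0, 25.0, 29.0, 20.0]},
        "noise_sd": 1.0,
        "n_reps": 3,
    },
}

# MADS-domain (CArG-box style) consensus placeholders for SVP/FLC/SOC1;
# real analyses should supply motif definitions from ChIP studies.
DEFAULT_TFBS = [
    {"name": "SVP_CArG", "motif": "CCWWWWWWGG"},
    {"name": "FLC_CArG", "motif": "CCAAAAATGG"},
    {"name": "SOC1_CArG", "motif": "CCWWWWWTGG"},
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with study-design defaults."""

    seed: int
    outdir: str
    synthetic: Optional[dict] = None
    inputs: Optional[dict] = None  # real-data mode: paths per input kind
    de: dict = field(default_factory=lambda: dict(DEFAULTS["de"]))
    clustering: dict = field(default_factory=lambda: dict(DEFAULTS["clustering"]))
    motifs: dict = field(default_factory=lambda: dict(DEFAULTS["motifs"]))
    context: dict = field(default_factory=lambda: dict(DEFAULTS["context"]))
    enrichment: dict = field(default_factory=lambda: dict(DEFAULTS["enrichment"]))
    tfbs_motifs: List[dict] = field(default_factory=lambda: [dict(m) for m in DEFAULT_TFBS])

    def __post_init__(self) -> None:
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config needs either a 'synthetic' block or 'inputs' paths")
        for name in ("de", "clustering", "motifs", "context", "enrichment"):
            merged = dict(DEFAULTS[name])
            merged.update(getattr(self, name) or {})
            setattr(self, name, merged)
        if self.synthetic is not None:
            merged = _deep_merge(DEFAULT_SYNTHETIC, self.synthetic)
            self.synthetic = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)


def _deep_merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _deep_merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    for k, v in override.items():
        if k not in out:
            out[k] = v
    return out


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Counter-based per-stage seed derivation (stable, below 2**31)."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as YAML)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "parameters": {}}
    files: Dict[str, Path] = {}

    # ---- stage 0: genome + lncRNA sources --------------------------------
    seed0 = stage_seed(config.seed, 0)
    syn = config.synthetic
    if syn is None:
        raise NotImplementedError(
            "real-data mode: run the per-stage functions on your own files; "
            "run_all currently orchestrates the synthetic study"
        )
    bundle = simulate.make_genome(
        syn["n_chrom"], syn["chrom_len"], syn["n_genes"], seed0)
    datasets, lnc_truth = simulate.make_lnc_sources(bundle, seed=seed0 + 1, **syn["lnc"])

    # ---- stage 1: atlas ---------------------------------------------------
    records = [r for ds in datasets for r in ds]
    atl = atlas_mod.merge_to_lnctus(records)
    units = atlas_mod.atlas_units(atl)

    # ---- stage 2: counts --------------------------------------------------
    seed2 = stage_seed(config.seed, 2)
    design = diffexpr.SampleDesign.default()
    profiles = np.asarray(syn["profiles"], dtype=float)
    features = [g.id for g in bundle.genes] + [u.id for u in units]
    counts, counts_truth = simulate.make_counts(
        features, design, profiles, seed=seed2, **syn["counts"])

    # ---- stage: promoters with planted motifs (before window extraction) --
    seed3 = stage_seed(config.seed, 3)
    gene_cluster = {g.id: counts_truth.planted_cluster_of_feature[g.id]
                    for g in bundle.genes}
    motif_truth = simulate.make_promoters(
        bundle, syn["motif_plants"], gene_cluster, seed=seed3)

    # emit simulation outputs now that sequences are final
    io.write_fasta(out / "genome.fa", bundle.sequences)
    io.write_genes_gff3(out / "genes.gff3", bundle.genes)
    for d, ds in enumerate(datasets):
        io.write_bed(out / f"lnc_src{d + 1}.bed",
                     [r.interval for r in ds], names=[r.record_id for r in ds])
    atlas_mod.write_atlas(atl, out / "atlas.bed", out / "atlas_members.tsv")
    io.write_counts_tsv(out / "counts.tsv", counts)
    design.to_frame().to_csv(out / "design.tsv", sep="\t", index=False)
    files.update({
        "genome": out / "genome.fa", "genes": out / "genes.gff3",
        "atlas": out / "atlas.bed", "atlas_members": out / "atlas_members.tsv",
        "counts": out / "counts.tsv", "design": out / "design.tsv",
    })
    for d in range(len(datasets)):
        files[f"lnc_src{d + 1}"] = out / f"lnc_src{d + 1}.bed"

    # ---- stage 4: differential expression --------------------------------
    de = diffexpr.run_de(counts, design, alpha=config.de["alpha"])
    de_table = de["table"]
    de_table.to_csv(out / "de_results.tsv", sep="\t", index=False)
    files["de_results"] = out / "de_results.tsv"

    # ---- stage 5: clustering ----------------------------------------------
    seed5 = stage_seed(config.seed, 5)
    de_feats = diffexpr.de_features(de_table)
    de_feats = [f for f in de_feats if f in de["filtered_counts"].index]
    clust_cfg = config.clustering
    prof = clustering.profile_transform(
        de["filtered_counts"].loc[de_feats], de["effective_libsizes"])
    k_max = min(clust_cfg["k_max"], max(1, len(de_feats) - 1))
    k_min = min(clust_cfg["k_min"], k_max)
    model, icl_table = clustering.select_k(
        prof, range(k_min, k_max + 1), n_restarts=clust_cfg["n_restarts"],
        seed=seed5)
    assignments = model.assignments()
    families = clustering.assign_families(
        model, design.timepoint_order, design.timepoints,
        theta=clust_cfg["theta"], theta_high=clust_cfg["theta_high"])
    assignments = assignments.merge(families[["cluster", "family"]], on="cluster")
    assignments.to_csv(out / "clusters.tsv", sep="\t", index=False)
    icl_table.to_csv(out / "icl_table.tsv", sep="\t", index=False)
    files["clusters"] = out / "clusters.tsv"
    files["icl_table"] = out / "icl_table.tsv"

    # hierarchical clustering of DE-lncTUs
    lnc_ids = {u.id for u in units}
    de_lnc = [f for f in de_feats if f in lnc_ids]
    if len(de_lnc) >= 2:
        linkage, labels = clustering.hclust_profiles(prof.loc[de_lnc], de_table)
        (out / "de_lnctus.nwk").write_text(
            clustering.linkage_to_newick(linkage, list(prof.loc[de_lnc].index)))
        labels.to_csv(out / "de_lnctu_labels.tsv", sep="\t", index=False)
        files["de_lnctus_newick"] = out / "de_lnctus.nwk"
        files["de_lnctu_labels"] = out / "de_lnctu_labels.tsv"

    # ---- stage 6: motifs --------------------------------------------------
    windows = plm.extract_windows(bundle.genes, bundle.sequences)
    mot_cfg = config.motifs
    plant_cluster = syn["motif_plants"][0]["cluster"] if syn["motif_plants"] else 0
    cluster_genes = [g for g, c in gene_cluster.items() if c == plant_cluster]
    cand = plm.discover(windows.subset(cluster_genes),
                        k_range=range(mot_cfg["k_min"], mot_cfg["k_max"] + 1),
                        alpha=mot_cfg["alpha"])
    motif_table = plm.candidates_table(cand)
    motif_table.to_csv(out / "plm_motifs.tsv", sep="\t", index=False)
    plm.long_motifs(motif_table).to_csv(out / "plm_motifs_7plus.tsv", sep="\t", index=False)
    files["plm_motifs"] = out / "plm_motifs.tsv"
    files["plm_motifs_7plus"] = out / "plm_motifs_7plus.tsv"

    # ---- stage 7: regulatory context --------------------------------------
    seed7 = stage_seed(config.seed, 7)
    ctx_cfg = config.context
    track = simulate.make_chromatin_states(bundle, seed=seed7)
    state_rows = []
    bias = syn.get("state_bias") or {}
    # place a dedicated biased lncTU set to exercise the planted association
    lengths = [(u.interval.chrom, min(u.interval.length,
                                      track.chrom_length(u.interval.chrom) - 1))
               for u in units]
    biased = simulate.place_intervals_with_bias(track, lengths, bias, seed=seed7 + 1)
    biased_units = [LncTU(iv, members=[]) for iv in biased]
    state_rows.append(context.state_enrichment(
        biased_units, track, n_shuffles=ctx_cfg["n_shuffles"],
        metric=ctx_cfg["metric"], seed=seed7 + 2, set_label="all"))
    enrich = pd.concat(state_rows, ignore_index=True)
    enrich.to_csv(out / "state_enrichment.tsv", sep="\t", index=False)
    files["state_enrichment"] = out / "state_enrichment.tsv"
    state_bed_iv = []
    state_bed_lab = []
    for chrom in track.boundaries:
        b = track.boundaries[chrom]
        for i, lab in enumerate(track.labels[chrom]):
            state_bed_iv.append((chrom, int(b[i]), int(b[i + 1]), lab))
    with open(out / "chromatin_states.bed", "w") as fh:
        for chrom, s, e, lab in state_bed_iv:
            fh.write(f"{chrom}\t{s}\t{e}\t{lab}\n")
    files["chromatin_states"] = out / "chromatin_states.bed"

    nat = context.find_nat_couples(units, bundle.genes, de_table)
    nat.to_csv(out / "nat_couples.tsv", sep="\t", index=False)
    files["nat_couples"] = out / "nat_couples.tsv"

    tf_motifs = pd.DataFrame(config.tfbs_motifs)
    de_lnc_units = [u for u in units if u.id in set(de_lnc)] or units[:20]
    hits = context.tfbs_scan(de_lnc_units, bundle.sequences, tf_motifs,
                             window_up=ctx_cfg["window_up"],
                             window_down=ctx_cfg["window_down"])
    hits.to_csv(out / "tfbs_hits.tsv", sep="\t", index=False)
    files["tfbs_hits"] = out / "tfbs_hits.tsv"

    # ---- stage 8: ploidy --------------------------------------------------
    seed8 = stage_seed(config.seed, 8)
    pl_cfg = syn["ploidy"]
    pl_table, pl_truth = simulate.make_ploidy(
        pl_cfg["profiles"], noise_sd=pl_cfg["noise_sd"],
        n_reps=pl_cfg["n_reps"], seed=seed8)
    pl_table = ploidy.ei_table(pl_table)
    pl_table.to_csv(out / "ploidy.tsv", sep="\t", index=False)
    files["ploidy"] = out / "ploidy.tsv"
    conds = list(pl_cfg["profiles"])
    pl_summary = ploidy.summarize_ei(
        pl_table, compare=tuple(conds[:2]) if len(conds) >= 2 else None)

    # ---- truth-vs-result report -------------------------------------------
    report = _truth_report(
        lnc_truth, counts_truth, motif_truth, units, de_table, de_feats,
        assignments, model.k, motif_table, nat, enrich, bias, pl_truth,
        pl_summary)
    with open(out / "truth_report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
    files["truth_report"] = out / "truth_report.yaml"

    manifest["parameters"] = {
        "de": config.de, "clustering": config.clustering,
        "motifs": config.motifs, "context": config.context,
        "enrichment": config.enrichment, "synthetic": _plain(syn),
    }
    manifest["stage_seeds"] = {i: stage_seed(config.seed, i) for i in range(9)}
    manifest["checksums"] = {k: _sha256(p) for k, p in sorted(files.items())}
    manifest["report"] = report
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_plain(manifest), fh, sort_keys=True)
    return manifest


def small_synthetic_config(seed: int, outdir) -> PipelineConfig:
    """Desk-scale synthetic study configuration.

    Same structure as the full analysis but with a reduced clustering
    sweep (K = 2..6): the synthetic study plants four profile clusters, so
    sweeping to K = 40 would spend almost all its time on models the data
    cannot support.
    """
    return PipelineConfig(
        seed=seed, outdir=str(outdir), synthetic={},
        clustering={"k_min": 2, "k_max": 6, "n_restarts": 5},
    )


def _plain(obj):
    """Recursively convert numpy scalars for clean YAML emission."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _truth_report(lnc_truth, counts_truth, motif_truth, units, de_table,
                  de_feats, assignments, k_selected, motif_table, nat,
                  enrich, bias, pl_truth, pl_summary) -> dict:
    from sklearn.metrics import adjusted_rand_score

    report: dict = {}

    # atlas: sort-sweep merge vs the generator's union-find truth
    report["atlas"] = {
        "n_lnctus": len(units),
        "truth_n_lnctus": int(lnc_truth.extras["n_lnctus_total"]),
        "match": len(units) == int(lnc_truth.extras["n_lnctus_total"]),
    }

    # DE recovery: planted |log2FC| >= 1 counts as truly DE in a contrast
    calls = de_table.set_index(["feature", "contrast"])["call"]
    tp = fp = fn = 0
    for (feat, contrast), true_lfc in counts_truth.planted_de.items():
        truly = np.isfinite(true_lfc) and abs(true_lfc) >= 1.0
        called = bool(calls.get((feat, contrast), False))
        tp += truly and called
        fp += (not truly) and called
        fn += truly and (not called)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    report["de"] = {"sensitivity": float(sens), "fdr": float(fdr),
                    "n_true": int(tp + fn), "n_called": int(tp + fp)}

    # clustering: ARI of the fitted labels vs planted clusters
    truth_labels = [counts_truth.planted_cluster_of_feature[f]
                    for f in assignments["feature"]]
    ari = adjusted_rand_score(truth_labels, assignments["cluster"])
    report["clustering"] = {"ari": float(ari), "k_selected": int(k_selected)}

    # motifs: rank of every planted motif among discovered candidates
    ranks = []
    for plant in motif_truth.planted_motifs:
        motif = plant["motif"]
        rank = None
        pval = None
        for i, row in motif_table.iterrows():
            if motif in row["members"].split(",") or row["consensus"] == motif:
                rank, pval = int(i) + 1, float(row["pvalue"])
                break
        ranks.append({"motif": motif, "window": plant["window"],
                      "rank": rank, "pvalue": pval})
    report["motifs"] = ranks

    # NAT: candidate recovery vs the generator's all-pairs truth
    truth_pairs = {(l, g) for l, g, _ in lnc_truth.planted_nat_pairs}
    found_pairs = {(r.lnctu, r.gene) for r in nat.itertuples(index=False)}
    report["nat"] = {
        "n_truth_candidates": len(truth_pairs),
        "n_found": len(found_pairs),
        "candidates_match": truth_pairs == found_pairs,
        "n_flagged_opposite": int(nat["flagged"].sum()) if len(nat) else 0,
    }

    # chromatin states: fold change of the biased state
    state_fc = {}
    for r in enrich.itertuples(index=False):
        state_fc[r.state] = {"fold_change": float(r.fold_change),
                             "p_enrich": float(r.p_enrich)}
    report["states"] = {"bias": {k: float(v) for k, v in bias.items()},
                        "fold_changes": state_fc}

    report["ploidy"] = {
        "truth_EI": {k: float(v) for k, v in pl_truth.items()},
        "measured": pl_summary["summary"].to_dict("records"),
    }
    if "welch" in pl_summary:
        w = pl_summary["welch"]
        report["ploidy"]["welch_p"] = float(w["p"])
    return _plain(report)
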