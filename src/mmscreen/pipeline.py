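"""End-to-end synthetic screen orchestration.

Ties the modules together into a deterministic pipeline: codebook and
mismatch-library design, clone bottlenecking, mother-machine lineage
simulation, phenotype extraction/aggregation/volcano, Z-score clustering,
growth-law classification and model fits, FISH decoding and read-group
consensus genotyping, ending in a joined genotype-phenotype table.  Every
stage draws its seed deterministically from the global seed, all outputs are
delimited text, and a manifest records a hash per artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import codec, consensus, design, growthlaws, lineage, phenotypes, clustering

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

#: knockdown archetypes cycled over simulated genes
GENE_ARCHETYPES: dict[str, dict[str, float]] = {
    "slow_long": {"growth_rate": 0.3, "added_length": 5.0},
    "slow_short": {"growth_rate": 0.4, "added_length": 1.6},
    "wide_slow": {"growth_rate": 0.6, "width": 1.4},
    "septum_noise": {"septum_sd": 0.12, "growth_rate": 0.9},
    "dim_reporter": {"intensity": 300.0, "growth_rate": 0.8},
    "arrest": {"growth_rate": 0.05, "intensity": 500.0},
}


@dataclass
class RunConfig:
    """Global configuration: one seed, all thresholds, stage toggles."""

    seed: int = 0
    n_genes: int = 6
    mismatch_levels: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    n_controls: int = 12
    n_trenches_per_sgrna: int = 8
    frame_interval_min: float = 10.0
    duration_h: float = 10.0
    induction_time_h: float = 2.0
    n_bits: int = 30
    fish_p_flip: float = 0.002
    read_depth: int = 20
    read_p_sub: float = 0.10
    n_read_groups: int = 50
    window_h: tuple[float, float] = (5.0, 8.0)  # post-induction aggregation window
    n_boot: int = 200
    gamma: float = 1.0
    resolution: float = 2.0
    k_neighbors: int = 10
    fdr: float = 0.05
    effect_sd_threshold: float = 2.0
    run_clustering: bool = True
    run_growthlaws: bool = True
    run_reads: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run the full synthetic screen; returns the in-memory artifacts.

    Writes tab-delimited tables plus ``manifest.json`` (stage hashes) under
    ``outdir``.  Identical configs produce byte-identical manifests.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    artifacts: dict = {}

    # --- library design -------------------------------------------------
    genes = {
        f"gene{i:02d}": dict(list(GENE_ARCHETYPES.values())[i % len(GENE_ARCHETYPES)])
        for i in range(cfg.n_genes)
    }
    strains = lineage.make_strain_effects(genes, list(cfg.mismatch_levels))
    strains += lineage.make_control_strains(cfg.n_controls)
    sgrna_ids = [s.sgrna_id for s in strains]

    # --- clone bottleneck + codebook ------------------------------------
    rng_clones = np.random.default_rng(stage_seed(cfg.seed, "clones"))
    n_clones = 4 * len(sgrna_ids)
    assignment = design.simulate_bottleneck(
        len(sgrna_ids), n_clones, seed=rng_clones
    )
    clone_table = assignment.table.copy()
    clone_table["sgrna_id"] = [sgrna_ids[i] for i in clone_table["sgrna_id"]]
    cb = codec.sample_codebook(
        n_clones, cfg.n_bits, seed=stage_seed(cfg.seed, "codebook")
    )
    lookup = clone_table.assign(
        bits=["".join(map(str, cb.bits[i])) for i in clone_table["barcode_id"]]
    )
    _write(lookup, out / "clone_lookup.tsv", manifest)
    artifacts["clone_lookup"] = lookup

    # --- lineage simulation ---------------------------------------------
    sim_cfg = lineage.SimConfig(
        frame_interval_min=cfg.frame_interval_min,
        duration_h=cfg.duration_h,
        induction_time_h=cfg.induction_time_h,
        n_trenches_per_sgrna=cfg.n_trenches_per_sgrna,
        seed=stage_seed(cfg.seed, "lineages"),
    )
    cells, truth = lineage.simulate_experiment(sim_cfg, strains)
    _write(truth, out / "ground_truth.tsv", manifest)
    artifacts["cells"] = cells
    artifacts["truth"] = truth

    # --- phenotyping ------------------------------------------------------
    extracted = phenotypes.extract_phenotypes(cells)
    rescaled = phenotypes.baseline_rescale(
        extracted, induction_time_min=cfg.induction_time_h * 60.0
    )
    window = (
        (cfg.induction_time_h + cfg.window_h[0]) * 60.0,
        (cfg.induction_time_h + cfg.window_h[1]) * 60.0,
    )
    lineage_means = phenotypes.window_lineage_means(rescaled.lineages, window)
    summaries = phenotypes.aggregate_sgrna(
        lineage_means, n_boot=cfg.n_boot, seed=stage_seed(cfg.seed, "bootstrap")
    )
    control_ids = [s.sgrna_id for s in strains if s.gene == "control"]
    volcano_table = phenotypes.volcano(
        lineage_means, summaries, control_ids,
        effect_sd_threshold=cfg.effect_sd_threshold, fdr=cfg.fdr,
    )
    _write(rescaled.dropped, out / "dropped_trenches.tsv", manifest)
    _write(summaries, out / "sgrna_summaries.tsv", manifest)
    _write(volcano_table, out / "volcano.tsv", manifest)
    artifacts["lineage_means"] = lineage_means
    artifacts["summaries"] = summaries
    artifacts["volcano"] = volcano_table

    # --- clustering -------------------------------------------------------
    if cfg.run_clustering:
        zset = clustering.zscore_timeseries(
            rescaled.lineages, control_ids, phenotypes.PARAMETERS
        )
        keep = [i for i in range(len(zset)) if clustering.weak_phenotype_filter(zset.values[i])]
        kept_ids = [zset.sgrna_ids[i] for i in keep]
        series = [zset.values[i] for i in keep]
        D = clustering.softdtw_matrix(series, gamma=cfg.gamma)
        labels = clustering.cluster(
            D, k_neighbors=cfg.k_neighbors, resolution=cfg.resolution,
            seed=stage_seed(cfg.seed, "leiden"),
        )
        label_table = pd.DataFrame({"sgrna_id": kept_ids, "cluster": labels})
        gene_of = {s.sgrna_id: s.gene for s in strains}
        label_table["gene"] = label_table["sgrna_id"].map(gene_of)
        gene_table = clustering.gene_assignment(label_table)
        gene_table["clusters"] = gene_table["clusters"].map(
            lambda cs: ",".join(map(str, cs))
        )
        _write(label_table, out / "clusters.tsv", manifest)
        _write(gene_table, out / "gene_clusters.tsv", manifest)
        artifacts["clusters"] = label_table
        artifacts["gene_clusters"] = gene_table

    # --- growth-law analysis ----------------------------------------------
    if cfg.run_growthlaws:
        rows = []
        for gene in list(genes) + ["control"]:
            sel = summaries[summaries["gene"] == gene]
            label, slope = growthlaws.classify_scaling(
                sel["growth_rate_estimate"].to_numpy(),
                sel["length_estimate"].to_numpy(),
            )
            rows.append({"gene": gene, "class": label, "slope": slope})
        scaling = pd.DataFrame(rows)
        _write(scaling, out / "scaling_classes.tsv", manifest)
        artifacts["scaling"] = scaling

        base = growthlaws.KineticParams()
        scans = {
            axis: growthlaws.perturbation_scan(base, axis)
            for axis in ("capture", "translocation", "initiation")
        }
        sector = growthlaws.SectorParams()
        class_points = {}
        for axis in ("capture", "translocation"):
            lam = scans[axis]["growth_rate"].to_numpy()
            V = growthlaws.volume_from_sectors(scans[axis]["phi_R"].to_numpy(), sector)
            class_points[axis] = (lam, V)
        fit = growthlaws.joint_fit(
            class_points, n_boot=cfg.n_boot, seed=stage_seed(cfg.seed, "jointfit")
        )
        fit_table = pd.DataFrame(
            [
                {"parameter": "u", "value": fit.u, "ci_lo": fit.ci["u"][0], "ci_hi": fit.ci["u"][1]},
                *[
                    {"parameter": f"w_{c}", "value": fit.slopes[c],
                     "ci_lo": fit.ci[c][0], "ci_hi": fit.ci[c][1]}
                    for c in fit.slopes
                ],
                *[
                    {"parameter": f"k_{c}", "value": fit.k[c],
                     "ci_lo": fit.ci[f"k_{c}"][0], "ci_hi": fit.ci[f"k_{c}"][1]}
                    for c in fit.k
                ],
            ]
        )
        _write(fit_table, out / "joint_fit.tsv", manifest)
        artifacts["joint_fit"] = fit
        artifacts["scans"] = scans

    # --- genotyping: FISH decode + read consensus --------------------------
    rng_fish = np.random.default_rng(stage_seed(cfg.seed, "fish"))
    err = codec.FishErrorModel(cfg.fish_p_flip, cfg.fish_p_flip)
    trench_clones = {}
    trench_ids = sorted(cells["trench_id"].unique())
    sg_by_trench = cells.groupby("trench_id")["sgrna_id"].first()
    clones_by_sg = clone_table.groupby("sgrna_id")["barcode_id"].apply(list)
    decode_rows = []
    for t in trench_ids:
        sg = sg_by_trench[t]
        if sg not in clones_by_sg.index:
            # the bottleneck can leave an sgRNA without any clone
            decode_rows.append(
                {"trench_id": t, "true_sgrna": sg, "decoded_sgrna": None, "correct": False}
            )
            continue
        clone = clones_by_sg[sg][rng_fish.integers(0, len(clones_by_sg[sg]))]
        trench_clones[t] = clone
        noisy = codec.simulate_readout(cb.bits[clone], err, rng_fish)
        res = codec.decode(noisy, cb)
        decoded_sg = (
            None
            if res.ambiguous
            else clone_table.loc[clone_table["barcode_id"] == res.barcode_id, "sgrna_id"].iloc[0]
        )
        decode_rows.append(
            {"trench_id": t, "true_sgrna": sg, "decoded_sgrna": decoded_sg,
             "correct": decoded_sg == sg}
        )
    genotype_table = pd.DataFrame(decode_rows)
    _write(genotype_table, out / "fish_genotypes.tsv", manifest)
    artifacts["fish_genotypes"] = genotype_table

    if cfg.run_reads:
        rng_reads = np.random.default_rng(stage_seed(cfg.seed, "reads"))
        pa, pb, variant_bases = consensus.make_variant_payloads(seed=rng_reads)
        read_err = consensus.ReadErrorModel(p_sub=cfg.read_p_sub)
        calls = []
        for gidx in range(cfg.n_read_groups):
            label = "A" if rng_reads.random() < 0.5 else "B"
            payload = pa if label == "A" else pb
            reads = consensus.simulate_reads(payload, cfg.read_depth, read_err, rng_reads)
            call = consensus.consensus_and_variant_call(reads, (500, 501), variant_bases)
            calls.append({"group": gidx, "true_variant": label, "call": call,
                          "correct": call == label})
        call_table = pd.DataFrame(calls)
        _write(call_table, out / "variant_calls.tsv", manifest)
        artifacts["variant_calls"] = call_table

    # --- genotype-phenotype join -------------------------------------------
    joined = genotype_table.merge(lineage_means, on="trench_id", how="inner")
    joined = joined[joined["decoded_sgrna"].notna()]
    by_decoded = (
        joined.groupby("decoded_sgrna")[
            [p for p in phenotypes.PARAMETERS if p in joined.columns]
        ]
        .median()
        .reset_index()
    )
    _write(by_decoded, out / "genotype_phenotype.tsv", manifest)
    artifacts["genotype_phenotype"] = by_decoded

    (out / "config.json").write_text(cfg.to_json())
    manifest["config.json"] = hashlib.sha256((out / "config.json").read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest
    return artifacts
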