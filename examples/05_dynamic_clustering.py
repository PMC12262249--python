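"""Cluster guides by the shape of their dynamic phenotype response.

Each guide's response is a 6-channel x 20-window Z-score timeseries against
control guides; soft-DTW compares trajectory shapes, Leiden groups them, and
jackknife resampling scores cluster stability.
"""

from mmscreen import clustering, lineage, phenotypes

cfg = lineage.SimConfig(n_trenches_per_sgrna=10, seed=12)
strains = (
    lineage.make_strain_effects({"slowA": {"growth_rate": 0.3}}, [0, 2, 4])
    + lineage.make_strain_effects({"wideB": {"width": 1.5, "growth_rate": 0.7}}, [0, 2, 4])
    + lineage.make_control_strains(12)
)
cells, _ = lineage.simulate_experiment(cfg, strains)
ex = phenotypes.extract_phenotypes(cells)
controls = [s.sgrna_id for s in strains if s.gene == "control"]

zset = clustering.zscore_timeseries(ex, controls, phenotypes.PARAMETERS)
keep = [i for i in range(len(zset)) if clustering.weak_phenotype_filter(zset.values[i])]
print(f"{len(zset)} guides -> {len(keep)} kept by the weak-phenotype filter (max|Z| > 1)")

series = [zset.values[i] for i in keep]
D = clustering.softdtw_matrix(series, gamma=1.0)
labels = clustering.cluster(D, k_neighbors=8, resolution=2.0, seed=13)
for sg, lab in zip([zset.sgrna_ids[i] for i in keep], labels):
    print(f"  {sg:12s} cluster {lab}")

rep = clustering.jackknife_stability(
    D, labels, n_resamples=20, seed=14, k_neighbors=8, resolution=2.0
)
print("jackknife stability (mean Jaccard / recall per cluster):")
print(rep.table.to_string(index=False))
# the two knockdown series form stable clusters (Jaccard ~ 1) while control
# guides scatter into small unstable ones -- stability, not cluster size, is
# what separates real response shapes from noise
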