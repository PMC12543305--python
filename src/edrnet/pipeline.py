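"""End-to-end pipeline orchestration with manifests.

Stages: simulate → measure → build → model → compare → asym → cluster.
Every stage writes its artifacts plus a JSON manifest (parameters, seeds,
package version) into the run directory; stages never mutate their inputs,
and a rerun with the same config reproduces deterministic outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .asymmetry import asymmetry_strengths, asymmetry_values, build_asymmetry_network
from .clustering import cut_clusters, feature_matrix, hier_cluster
from .edr_model import DEFAULT_LAMBDA_GRID, EDRModel
from .projectome import build_projectome
from .skeleton_metrics import arbor_consistency_filter, fit_edr, measure_cohort, scaling_factor
from .synthetic import AtlasSpec, SyntheticTruth, make_atlas, make_projectome, make_skeletons, make_synapse_table


@dataclass
class RunConfig:
    """Configuration of a full synthetic-data pipeline run."""

    out_dir: str
    seed: int = 0
    n_pairs: int = 37
    n_central: int = 1
    lambda_true_per_mm: float = 33.0
    tortuosity_a: float = 1.5
    n_neurons: int = 2000
    M: int = 2000
    beta: float = 0.0
    threshold_mm: float = 0.15
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    n_networks: int = 20
    k_clusters: int = 4
    min_synapses: int = 5
    bin_sizes_mm: tuple = (0.01, 0.02, 0.05)
    extra: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def manifest(stage, **params):
        io.write_json(
            dict(stage=stage, version=__version__, seed=config.seed, **params),
            out / f"{stage}.manifest.json",
        )

    # simulate ---------------------------------------------------------------
    atlas_spec = AtlasSpec(config.n_pairs, config.n_central, seed=config.seed)
    atlas = make_atlas(atlas_spec)
    rng = np.random.default_rng(config.seed + 1)
    profile = rng.uniform(0, 1, atlas.n_regions) if config.beta else None
    truth = SyntheticTruth(
        lambda_true_per_mm=config.lambda_true_per_mm,
        tortuosity_a=config.tortuosity_a,
        asym_profile=tuple(profile) if profile is not None else None,
        seed=config.seed,
    )
    skeletons, truth_table = make_skeletons(atlas, truth, config.n_neurons)
    synapses, classes = make_synapse_table(skeletons, atlas)
    io.write_atlas_csv(atlas, out / "atlas.csv")
    io.write_tsv(truth_table, out / "truth.tsv")
    io.write_tsv(synapses, out / "synapses.tsv")
    io.write_tsv(classes, out / "classes.tsv")
    manifest("simulate", atlas_spec=asdict(atlas_spec), n_neurons=config.n_neurons,
             lambda_true=config.lambda_true_per_mm, tortuosity_a=config.tortuosity_a,
             beta=config.beta, M=config.M)

    # measure ----------------------------------------------------------------
    records = measure_cohort(skeletons)
    records, filt = arbor_consistency_filter(records, config.threshold_mm)
    kept = records[records["kept"]]
    fit = fit_edr(kept["cable_mm"], config.bin_sizes_mm)
    slope_a, pearson_r = scaling_factor(kept["cable_mm"], kept["euclid_mm"])
    io.write_tsv(records, out / "cable_records.tsv")
    io.write_json(
        dict(
            lambda_per_mm=fit.lambda_per_mm,
            lambda_interval=list(fit.lambda_interval),
            per_bin_size={str(k): v for k, v in fit.per_bin_size.items()},
            scaling_factor=slope_a,
            pearson_r=pearson_r,
            filter_summary=filt,
        ),
        out / "edr_fit.json",
    )
    manifest("measure", threshold_mm=config.threshold_mm, bin_sizes=list(config.bin_sizes_mm))

    # build ------------------------------------------------------------------
    proj = build_projectome(synapses, classes, atlas, min_synapses=config.min_synapses)
    io.write_network_csv(proj.w, proj.labels, out / "projectome_w.csv")
    io.write_edge_list(proj.w, proj.labels, out / "projectome_edges.tsv")
    io.write_network_csv(atlas.distance_matrix(), atlas.labels, out / "distances_mm.csv")
    manifest("build", M=proj.M, density_percent=proj.density_percent)

    # model + compare --------------------------------------------------------
    # The measured projectome is sparse when few neurons are simulated; the
    # EDR-generated synthetic projectome carries the full link-count target.
    model_proj = make_projectome(atlas, truth, config.M, beta=config.beta)
    model = EDRModel(model_proj, atlas=atlas)
    results = model.fit(config.lambda_grid, n_networks=config.n_networks, seed=config.seed)
    (out / "edr_model_summary.txt").write_text(results.summary() + "\n")
    results.curve.to_csv(out / "rmsd_curves.csv", index=False)
    manifest("compare", lambda_grid=list(config.lambda_grid),
             n_networks=config.n_networks, lambda_opt=results.lambda_opt_)

    # asym -------------------------------------------------------------------
    vals = asymmetry_values(model_proj.w, model_proj.labels)
    net = build_asymmetry_network(model_proj.w, model_proj.labels)
    ranking = asymmetry_strengths(net)
    io.write_tsv(ranking, out / "asymmetry_ranking.tsv")
    io.write_edge_list(net.S, net.labels, out / "asymmetry_edges.tsv")
    manifest("asym", n_bidirectional_pairs=int(len(vals)),
             mean_asym=float(np.mean(vals)) if len(vals) else None)

    # cluster ----------------------------------------------------------------
    fm = feature_matrix(model_proj.w, labels=model_proj.labels)
    dend = hier_cluster(fm)
    part = cut_clusters(dend, config.k_clusters)
    io.write_tsv(
        __import__("pandas").DataFrame(dict(label=model_proj.labels, cluster=part)),
        out / "clusters.tsv",
    )
    manifest("cluster", k=config.k_clusters, linkage="ward", metric="euclidean",
             fill_value=fm.fill_value)

    return out
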