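"""End-to-end orchestration: simulate or load, preprocess, build networks,
characterize, test, and write a deterministic JSON summary.

``run_pipeline`` sequences the stages on two subject panels (either loaded
from TSV files or drawn from the synthetic cohort generator), writing every
intermediate artifact so any stage can be re-run independently.  The JSON
summary is byte-identical across runs with the same configuration and seed.

``extract_roi_means`` converts an image + integer label atlas (NIfTI or
arrays) into the per-region mean vector the table pipeline consumes; the
core pipeline itself is table-in / table-out.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .atlas import association_paralimbic_fraction, classify_composition, load_region_table
from .inference import (
    centrality_distribution_correlation,
    format_density_ranges,
    global_permutation_test,
    nodal_permutation_test,
)
from .io import read_panel, write_json, write_matrix, write_panel, write_residual_panel
from .metrics import identify_hubs, nodal_centrality, shared_hubs, small_world
from .network import (
    density_sweep,
    largest_component_size,
    min_full_connection_density,
    pearson_matrix,
    sweep_densities,
)
from .preprocess import DEFAULT_COVARIATES, SubjectPanel, global_normalize, residualize
from .simulate import CohortSpec, generate_cohort


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``values_a``/``covariates_a`` (+ the ``_b`` pair) point at panel
    TSVs, or ``simulate`` carries a :class:`CohortSpec`-shaped dict and the
    cohort is generated.  Round-trips losslessly through JSON.
    """

    out_dir: str = "metabnet_run"
    seed: int = 0
    values_a: Optional[str] = None
    covariates_a: Optional[str] = None
    values_b: Optional[str] = None
    covariates_b: Optional[str] = None
    simulate: Optional[dict] = None
    d_min: float = 0.10
    d_max: float = 0.40
    d_step: float = 0.01
    nodal_density: float = 0.10
    n_perm: int = 1000
    alpha: float = 0.05
    hub_threshold: float = 1.5
    n_random_refs: int = 100
    n_random_refs_perm: int = 10
    covariate_set: Sequence[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    perm_metrics: Sequence[str] = field(default_factory=lambda: ["gamma", "lambda", "sigma"])

    def validate(self) -> None:
        if not 0 < self.d_min <= self.d_max < 1:
            raise ValueError("density range must satisfy 0 < d_min <= d_max < 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 20:
            raise ValueError("n_perm must be at least 20")
        has_files = all(
            v is not None
            for v in (self.values_a, self.covariates_a, self.values_b, self.covariates_b)
        )
        if not has_files and self.simulate is None:
            raise ValueError("config needs either panel file paths or a simulate block")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        import json

        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        write_json(asdict(self), path)


def extract_roi_means(image, atlas_labels, n_regions: Optional[int] = None) -> np.ndarray:
    """Mean image intensity over the voxels of each atlas label.

    ``image`` and ``atlas_labels`` may be file paths, nibabel images, or
    arrays.  Labels must be the integers ``1..n_regions`` in canonical
    region order; a label with zero voxels, an unknown label, or mismatched
    grids raise an error.
    """
    img_data, img_affine = _load_volume(image)
    lab_data, lab_affine = _load_volume(atlas_labels)
    if img_data.shape != lab_data.shape:
        raise ValueError(
            f"image grid {img_data.shape} != atlas grid {lab_data.shape}"
        )
    if img_affine is not None and lab_affine is not None:
        if not np.allclose(img_affine, lab_affine, atol=1e-4):
            raise ValueError("image and atlas affines disagree")
    labels = lab_data.astype(int)
    if not np.allclose(lab_data, labels):
        raise ValueError("atlas labels must be integers")
    present = np.unique(labels)
    present = present[present > 0]
    if n_regions is None:
        n_regions = int(present.max()) if len(present) else 0
    if len(present) and present.max() > n_regions:
        raise ValueError(f"unknown atlas label {int(present.max())} (> {n_regions})")
    means = np.empty(n_regions)
    for r in range(1, n_regions + 1):
        mask = labels == r
        if not mask.any():
            raise ValueError(f"atlas label {r} has no voxels")
        means[r - 1] = float(img_data[mask].mean())
    return means


def _load_volume(source) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if isinstance(source, (str, Path)):
        import nibabel as nib

        img = nib.load(str(source))
        return np.asarray(img.get_fdata()), img.affine
    if hasattr(source, "get_fdata"):
        return np.asarray(source.get_fdata()), getattr(source, "affine", None)
    return np.asarray(source), None


def _load_or_simulate(config: RunConfig):
    if config.simulate is not None:
        spec = CohortSpec(**{**config.simulate, "seed": config.seed})
        labels = None
        if spec.n_regions == 90:
            labels = load_region_table().labels
        panel_a, panel_b, _ = generate_cohort(spec, region_labels=labels)
        return panel_a, panel_b
    panel_a = read_panel(config.values_a, config.covariates_a)
    panel_b = read_panel(config.values_b, config.covariates_b)
    return panel_a, panel_b


def _group_stage(panel: SubjectPanel, config: RunConfig, out: Path, tag: str):
    """normalize -> residualize -> correlation -> sweep for one group."""
    covs = tuple(config.covariate_set)
    res = residualize(global_normalize(panel), covs)
    write_residual_panel(res, out / f"residuals_{tag}.tsv", out / f"coefficients_{tag}.json")
    corr = pearson_matrix(res)
    write_matrix(corr.r, corr.labels, out / f"correlation_{tag}.tsv")
    nets = density_sweep(corr, config.d_min, config.d_max, config.d_step)
    return res, corr, nets


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return (and write) the JSON summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")

    panel_a, panel_b = _load_or_simulate(config)
    if config.simulate is not None:
        write_panel(panel_a, out / "values_A.tsv", out / "covariates_A.tsv")
        write_panel(panel_b, out / "values_B.tsv", out / "covariates_B.tsv")

    region_table = None
    if panel_a.n_regions == 90:
        region_table = load_region_table()
        if panel_a.region_labels != region_table.labels:
            region_table = None  # non-atlas labels: skip hub annotation

    densities = sweep_densities(config.d_min, config.d_max, config.d_step)
    rng = np.random.default_rng(config.seed)
    summary: dict = {
        "version": __version__,
        "config": asdict(config),
        "groups": {},
    }

    nodal_b = {}
    for tag, panel in (("A", panel_a), ("B", panel_b)):
        res, corr, nets = _group_stage(panel, config, out, tag)
        globals_per_density = []
        for net in nets:
            gm = small_world(
                net,
                n_random=config.n_random_refs,
                seed=int(rng.integers(2**31)),
                on_disconnected="connected_pairs",
            )
            globals_per_density.append(
                {
                    "density": net.density,
                    "largest_component": largest_component_size(net),
                    "C": gm.C,
                    "L": gm.L,
                    "gamma": gm.gamma,
                    "lambda": gm.lambda_,
                    "sigma": gm.sigma,
                    "n_disconnected_refs": gm.n_disconnected_refs,
                }
            )
        nodal_net = next(
            (n for n, d in zip(nets, densities) if abs(d - config.nodal_density) < 1e-9),
            None,
        )
        if nodal_net is None:
            from .network import density_threshold

            nodal_net = density_threshold(corr, config.nodal_density)
        nc = nodal_centrality(nodal_net)
        nc.to_frame().to_csv(out / f"nodal_{tag}.tsv", sep="\t", index_label="region")
        nodal_b[tag] = nc.b
        group_summary = {
            "n_subjects": panel.n_subjects,
            "min_full_connection_density": min_full_connection_density(corr, densities),
            "global_metrics": globals_per_density,
        }
        if region_table is not None:
            hubs = identify_hubs(nc, region_table, config.hub_threshold)
            comp_n, comp_frac = (
                association_paralimbic_fraction(hubs.regions) if len(hubs) else (0, 0.0)
            )
            group_summary["hubs"] = [
                {
                    "region": r.label,
                    "name": str(r),
                    "func_class": r.func_class,
                    "b": b,
                }
                for r, b in hubs
            ]
            group_summary["hub_composition"] = {
                fc: {"count": c, "fraction": f}
                for fc, (c, f) in (
                    classify_composition(hubs.regions).items() if len(hubs) else []
                )
            }
            group_summary["association_paralimbic"] = {
                "count": comp_n,
                "fraction": comp_frac,
            }
            group_summary["hub_set"] = hubs
        summary["groups"][tag] = group_summary

    if region_table is not None:
        shared = shared_hubs(
            summary["groups"]["A"].pop("hub_set"), summary["groups"]["B"].pop("hub_set")
        )
        summary["shared_hubs"] = [r.label for r in shared]
    else:
        for tag in ("A", "B"):
            summary["groups"][tag].pop("hub_set", None)

    r, p = centrality_distribution_correlation(nodal_b["A"], nodal_b["B"])
    summary["centrality_distribution_correlation"] = {"r": r, "p": p}

    global_res = global_permutation_test(
        panel_a,
        panel_b,
        densities=densities,
        metrics=tuple(config.perm_metrics),
        n_perm=config.n_perm,
        alpha=config.alpha,
        n_random_refs=config.n_random_refs_perm,
        seed=int(rng.integers(2**31)),
        covariates=tuple(config.covariate_set),
    )
    global_frame = global_res.to_frame()
    global_frame.to_csv(out / "permutation_global.tsv", sep="\t", index_label="statistic")
    sig_ranges = {}
    for metric in config.perm_metrics:
        flags = [
            bool(global_frame.loc[f"{metric}@{d:g}", "significant"]) for d in densities
        ]
        sig_ranges[metric] = format_density_ranges(densities, flags)
    summary["global_permutation"] = {
        "n_perm": global_res.n_perm,
        "alpha": global_res.alpha,
        "n_random_refs": config.n_random_refs_perm,
        "significant_densities": sig_ranges,
    }

    nodal_res = nodal_permutation_test(
        panel_a,
        panel_b,
        density=config.nodal_density,
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=int(rng.integers(2**31)),
        covariates=tuple(config.covariate_set),
    )
    nodal_frame = nodal_res.to_frame()
    nodal_frame.to_csv(out / "permutation_nodal.tsv", sep="\t", index_label="region")
    summary["nodal_permutation"] = {
        "density": config.nodal_density,
        "n_perm": nodal_res.n_perm,
        "decreased_in_A": [
            n for n, f in zip(nodal_res.names, nodal_res.significant_decrease) if f
        ],
        "increased_in_A": [
            n for n, f in zip(nodal_res.names, nodal_res.significant_increase) if f
        ],
    }

    write_json(summary, out / "summary.json")
    write_json(
        {"version": __version__, "seed": config.seed, "config": asdict(config)},
        out / "run_log.json",
    )
    return summary
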