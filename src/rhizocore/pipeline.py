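"""Study orchestration: simulate ensembles, core them, evaluate strategies.

Runs the full in-silico design at configurable scale: for each species and
phenotype an ensemble of plots is simulated (phenotypes share a replicate
seed sequence, so total root length is phenotype-invariant), virtual cores
are extracted at the six named locations plus one random location per
replicate, and whole-plot truth profiles recorded.  Downstream analyses —
TOST equivalence matrices, Manhattan-distance subset rankings, depth
metrics, resampling power curves and QDA misclassification tables — are
emitted as tidy CSVs with a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rhizocore import coring, depth, layout as layout_mod, simulate, stats

logger = logging.getLogger(__name__)

ALL_LOCATIONS = (1, 2, 3, 4, 5, 6)
QDA_LOCATIONS = (1, 2, 3, 4, 5, 6)  # 4 and 5 are skipped when rank-deficient
DEPTH_PS = (50.0, 80.0, 90.0, 95.0)

CORE_TABLE_COLUMNS = [
    "species",
    "phenotype",
    "replicate",
    "location",
    "depth_top_cm",
    "depth_bottom_cm",
    "root_length_cm",
    "rld_cm_cm3",
]


@dataclass
class StudyConfig:
    """Configuration for one end-to-end study run."""

    species: tuple[str, ...] = ("maize", "bean")
    phenotypes: tuple[str, ...] = ("shallow", "intermediate", "deep")
    n_replicates: int = 25
    scale: str = "test"  # test | full (full forces 100 replicates)
    subset_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    seed: int = 0
    tost: stats.TOSTConfig = field(default_factory=stats.TOSTConfig)
    qda_training_sizes: tuple[int, ...] = (8, 10, 15, 20, 25, 30, 35, 40, 45, 50)
    qda_n_test: int = 50
    qda_n_draws: int = 20
    power_n_range: tuple[int, ...] = tuple(range(2, 21))
    power_reps: int = 2000
    alpha: float = 0.05
    outdir: str = "study_output"

    def __post_init__(self) -> None:
        if self.scale == "full":
            self.n_replicates = max(self.n_replicates, 100)
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not set(self.subset_sizes) <= set(range(1, 7)):
            raise ValueError("subset sizes must be within 1..6")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "tost" in raw:
            raw["tost"] = stats.TOSTConfig(**raw["tost"])
        for key in ("species", "phenotypes", "subset_sizes", "qda_training_sizes", "power_n_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SubsetRanking:
    """Mean Manhattan distance to a reference, per location subset, ranked."""

    reference: str  # whole_plot | voronoi_all6
    method: str  # voronoi | unadjusted
    table: pd.DataFrame  # columns: subset_size, subset, mean_distance, sd_distance, rank

    def top(self, size: int, k: int = 3) -> pd.DataFrame:
        sub = self.table[self.table.subset_size == size]
        return sub.nsmallest(k, "mean_distance")


@dataclass
class SpeciesData:
    """Per-replicate arrays for one species: truth and per-location core RLD."""

    species: str
    layout: layout_mod.CoringLayout
    depth_bins: tuple[float, ...]
    truth: dict[str, np.ndarray]  # phenotype -> (reps, bins) whole-plot RLD
    core_rld: dict[str, dict[int | str, np.ndarray]]  # phenotype -> loc -> (reps, bins)
    core_rl: dict[str, dict[int | str, np.ndarray]]  # root length per bin
    total_root_length: dict[str, np.ndarray]  # phenotype -> (reps,)

    @property
    def n_replicates(self) -> int:
        return next(iter(self.truth.values())).shape[0]


def simulate_species(
    species: str,
    phenotypes: Sequence[str],
    n_replicates: int,
    seed: int,
    depth_bins: Sequence[float] = coring.DEFAULT_DEPTH_BINS,
) -> SpeciesData:
    """Simulate ensembles for all phenotypes of one species and core them.

    All phenotypes reuse one replicate seed sequence (paired stochastic
    draws), and the random coring location of a replicate is shared across
    phenotypes as well.
    """
    lay = layout_mod.default_layout(species)
    species_tag = int.from_bytes(hashlib.sha256(species.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([seed, species_tag])
    rep_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_replicates)]
    rand_rng = np.random.default_rng(ss.spawn(1)[0])
    bins = tuple(float(b) for b in depth_bins)

    specs = {
        loc: coring.CoreSpec(center=xy, depth_bins=bins, location_id=loc)
        for loc, xy in lay.locations.items()
    }

    truth: dict[str, np.ndarray] = {}
    core_rld: dict[str, dict] = {}
    core_rl: dict[str, dict] = {}
    totals: dict[str, np.ndarray] = {}
    n_bins = len(bins) - 1

    # random core centers shared across phenotypes, one per replicate
    R, P = lay.row_spacing, lay.plant_spacing
    rand_centers = [
        (rand_rng.uniform(-R / 2, R / 2), rand_rng.uniform(-P / 2, P / 2))
        for _ in range(n_replicates)
    ]

    for phen in phenotypes:
        config = simulate.SimConfig.for_study(species, phen)
        ensemble = simulate.study_ensemble(config, n_replicates, seed_sequence=rep_seeds)
        truth[phen] = np.empty((n_replicates, n_bins))
        core_rld[phen] = {loc: np.empty((n_replicates, n_bins)) for loc in list(specs) + ["random"]}
        core_rl[phen] = {loc: np.empty((n_replicates, n_bins)) for loc in list(specs) + ["random"]}
        totals[phen] = np.empty(n_replicates)
        for i, plot in enumerate(ensemble):
            totals[phen][i] = plot.total_root_length
            truth[phen][i] = coring.whole_plot_profile(plot, bins).rld_by_bin
            for loc, spec in specs.items():
                sample = coring.extract_core(plot, spec)
                core_rld[phen][loc][i] = sample.rld_by_bin
                core_rl[phen][loc][i] = sample.root_length_by_bin
            rspec = coring.CoreSpec(center=rand_centers[i], depth_bins=bins, location_id="random")
            rsample = coring.extract_core(plot, rspec)
            core_rld[phen]["random"][i] = rsample.rld_by_bin
            core_rl[phen]["random"][i] = rsample.root_length_by_bin

    return SpeciesData(
        species=species,
        layout=lay,
        depth_bins=bins,
        truth=truth,
        core_rld=core_rld,
        core_rl=core_rl,
        total_root_length=totals,
    )


def _estimate_matrix(
    data: SpeciesData, phen: str, subset: Sequence[int], method: str
) -> np.ndarray:
    """Per-replicate estimate profiles (reps, bins) for a location subset."""
    stack = np.stack([data.core_rld[phen][loc] for loc in subset], axis=0)  # (k, reps, bins)
    if method == "unadjusted":
        return stack.mean(axis=0)
    if method == "voronoi":
        weights = layout_mod.voronoi_weights(data.layout, subset)
        w = np.array([weights.w[loc] for loc in subset])
        return np.einsum("k,krb->rb", w, stack)
    raise ValueError(f"unknown method {method!r}")


def tost_equivalence_matrix(
    species_data: Mapping[str, SpeciesData],
    tost_config: stats.TOSTConfig | None = None,
) -> pd.DataFrame:
    """Per-cell TOST equivalence of both estimators against whole-plot truth.

    Cells are species x phenotype x depth bin; estimators use all six
    locations.  Returns a tidy frame with one row per cell per method.
    """
    cfg = tost_config or stats.TOSTConfig()
    rows = []
    for species, data in species_data.items():
        for phen in data.truth:
            truth = data.truth[phen]
            for method in ("unadjusted", "voronoi"):
                est = _estimate_matrix(data, phen, ALL_LOCATIONS, method)
                for b in range(truth.shape[1]):
                    try:
                        res = stats.tost_equivalence(est[:, b], truth[:, b], cfg)
                        p, eq = res.p_value, res.equivalent
                    except stats.ZeroVarianceError:
                        p, eq = 1.0, False
                    rows.append(
                        {
                            "species": species,
                            "phenotype": phen,
                            "depth_top_cm": data.depth_bins[b],
                            "depth_bottom_cm": data.depth_bins[b + 1],
                            "method": method,
                            "p_value": p,
                            "equivalent": eq,
                        }
                    )
    return pd.DataFrame(rows)


def equivalence_counts(matrix: pd.DataFrame) -> dict[str, int]:
    """Number of equivalent cells per estimator over the species x phenotype x depth grid."""
    return matrix.groupby("method")["equivalent"].sum().astype(int).to_dict()


def evaluate_subsets(
    data: SpeciesData,
    reference: str = "whole_plot",
    method: str = "voronoi",
    subset_sizes: Sequence[int] = (1, 2, 3, 4, 5),
    phenotypes: Sequence[str] | None = None,
) -> SubsetRanking:
    """Rank location subsets by mean Manhattan distance to a reference profile.

    ``reference`` is "whole_plot" (per-replicate truth) or "voronoi_all6"
    (per-replicate 6-location Voronoi estimate).  Distances are computed per
    replicate and averaged over replicates and phenotypes.
    """
    phens = list(phenotypes) if phenotypes is not None else list(data.truth)
    refs = {}
    for phen in phens:
        if reference == "whole_plot":
            refs[phen] = data.truth[phen]
        elif reference == "voronoi_all6":
            refs[phen] = _estimate_matrix(data, phen, ALL_LOCATIONS, "voronoi")
        else:
            raise ValueError(f"unknown reference {reference!r}")

    rows = []
    for size in subset_sizes:
        for subset in itertools.combinations(ALL_LOCATIONS, size):
            dists = []
            for phen in phens:
                est = _estimate_matrix(data, phen, subset, method)
                dists.append(np.abs(est - refs[phen]).sum(axis=1))
            dists = np.concatenate(dists)
            rows.append(
                {
                    "subset_size": size,
                    "subset": "+".join(map(str, subset)),
                    "mean_distance": float(dists.mean()),
                    "sd_distance": float(dists.std(ddof=1)),
                }
            )
    table = pd.DataFrame(rows).sort_values(["subset_size", "mean_distance"]).reset_index(drop=True)
    table["rank"] = table.groupby("subset_size")["mean_distance"].rank(method="first").astype(int)
    return SubsetRanking(reference=reference, method=method, table=table)


def depth_metric_table(data: SpeciesData, ps: Sequence[float] = DEPTH_PS) -> pd.DataFrame:
    """Tidy D_p values per core and for the whole-plot truth."""
    rows = []
    for phen in data.truth:
        for loc in list(ALL_LOCATIONS) + ["random"]:
            rl = data.core_rl[phen][loc]
            for i in range(rl.shape[0]):
                if rl[i].sum() <= 0:
                    continue
                for p in ps:
                    metric = depth.depth_quantile(rl[i], p)
                    rows.append(
                        {
                            "species": data.species,
                            "phenotype": phen,
                            "location": loc,
                            "replicate": i,
                            "p": p,
                            "depth_cm": metric.value,
                        }
                    )
        truth = data.truth[phen]
        for i in range(truth.shape[0]):
            prof = coring.RLDProfile(rld_by_bin=truth[i], depth_bins=data.depth_bins)
            for p in ps:
                rows.append(
                    {
                        "species": data.species,
                        "phenotype": phen,
                        "location": "whole_plot",
                        "replicate": i,
                        "p": p,
                        "depth_cm": depth.depth_quantile(prof, p).value,
                    }
                )
    return pd.DataFrame(rows)


def power_analysis(
    data: SpeciesData,
    ps: Sequence[float] = DEPTH_PS,
    n_range: Sequence[int] = tuple(range(2, 21)),
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    locations: Sequence[int | str] | None = None,
) -> pd.DataFrame:
    """Power curves for every location and depth metric."""
    locs = list(locations) if locations is not None else list(ALL_LOCATIONS) + ["random"]
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    for loc in locs:
        for p in ps:
            pools = {}
            redraws = 0
            for phen in data.truth:
                rl = data.core_rl[phen][loc]
                totals = rl.sum(axis=1)
                ok = totals > 0
                redraws += int((~ok).sum())
                vals = [depth.depth_quantile(rl[i], p).value for i in np.flatnonzero(ok)]
                pools[phen] = np.asarray(vals)
            if any(len(v) < 2 for v in pools.values()):
                logger.warning("location %s: too few non-empty cores for power analysis", loc)
                continue
            curve = stats.resampling_power(
                pools, loc, p, n_range=n_range, reps=reps, alpha=alpha, rng=rng, redraws=redraws
            )
            for n, prop in zip(curve.sample_sizes, curve.proportion_significant):
                rows.append(
                    {
                        "species": data.species,
                        "location": loc,
                        "p": p,
                        "cores_per_phenotype": int(n),
                        "proportion_significant": float(prop),
                        "n_resamples": reps,
                        "redraws": redraws,
                    }
                )
    return pd.DataFrame(rows)


def qda_tables(
    data: SpeciesData,
    training_sizes: Sequence[int] = (8, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    n_test: int = 50,
    n_draws: int = 20,
    seed: int = 0,
    locations: Sequence[int] = QDA_LOCATIONS,
) -> pd.DataFrame:
    """Misclassification sweeps per location for 3-class and shallow-vs-deep QDA.

    Locations whose class covariances are rank-deficient (typically the
    mid-row locations, where shallow layers recover few roots) are skipped
    with a log message, mirroring the study protocol.
    """
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    variants = {
        "three_class": list(data.truth.keys()),
        "two_class": [p for p in data.truth if p in ("shallow", "deep")],
    }
    for loc in locations:
        for variant, phens in variants.items():
            if len(phens) < 2:
                continue
            class_vectors = {phen: data.core_rld[phen][loc] for phen in phens}
            try:
                sweep = stats.qda_experiment(
                    class_vectors,
                    training_sizes=training_sizes,
                    n_test=n_test,
                    n_draws=n_draws,
                    rng=rng,
                    context=f"{data.species} location {loc}",
                )
            except stats.RankDeficiencyError as err:
                logger.info("QDA skipped at %s location %s: %s", data.species, loc, err)
                continue
            for _, r in sweep.iterrows():
                rows.append(
                    {
                        "species": data.species,
                        "location": loc,
                        "variant": variant,
                        "training_size": int(r.training_size),
                        "misclassification": r.misclassification,
                        "se": r.se,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Core-sample table I/O (also the reader target for field data)
# --------------------------------------------------------------------------

def cores_to_dataframe(species_data: Mapping[str, SpeciesData]) -> pd.DataFrame:
    rows = []
    for species, data in species_data.items():
        bins = data.depth_bins
        for phen in data.core_rl:
            for loc in data.core_rl[phen]:
                rl = data.core_rl[phen][loc]
                rld = data.core_rld[phen][loc]
                for i in range(rl.shape[0]):
                    for b in range(rl.shape[1]):
                        rows.append(
                            {
                                "species": species,
                                "phenotype": phen,
                                "replicate": i,
                                "location": str(loc),
                                "depth_top_cm": bins[b],
                                "depth_bottom_cm": bins[b + 1],
                                "root_length_cm": rl[i, b],
                                "rld_cm_cm3": rld[i, b],
                            }
                        )
    return pd.DataFrame(rows, columns=CORE_TABLE_COLUMNS)


def write_core_table(samples: Sequence[coring.CoreSample], path) -> None:
    """Serialize CoreSamples to the documented CSV schema."""
    rows = []
    for s in samples:
        for b in range(len(s.depth_bins) - 1):
            rows.append(
                {
                    "species": s.species,
                    "phenotype": s.phenotype,
                    "replicate": s.replicate_id,
                    "location": str(s.location_id),
                    "depth_top_cm": s.depth_bins[b],
                    "depth_bottom_cm": s.depth_bins[b + 1],
                    "root_length_cm": s.root_length_by_bin[b],
                    "rld_cm_cm3": s.rld_by_bin[b],
                }
            )
    pd.DataFrame(rows, columns=CORE_TABLE_COLUMNS).to_csv(path, index=False)


class CoreTableError(ValueError):
    """Malformed core-sample table."""


def read_core_table(path) -> list[coring.CoreSample]:
    """Read a core-sample CSV into CoreSamples grouped by species/phenotype/replicate/location.

    Validates the schema: required columns, non-negative lengths, and
    contiguous strictly-increasing depth bins within each group; offending
    rows are reported with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in CORE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CoreTableError(f"missing required columns: {missing}")
    bad = df.index[df["root_length_cm"] < 0]
    if len(bad):
        raise CoreTableError(f"negative root_length_cm at line {int(bad[0]) + 2}")
    bad = df.index[df["rld_cm_cm3"] < 0]
    if len(bad):
        raise CoreTableError(f"negative rld_cm_cm3 at line {int(bad[0]) + 2}")

    samples = []
    keys = ["species", "phenotype", "replicate", "location"]
    for (species, phen, rep, loc), group in df.groupby(keys, sort=True):
        group = group.sort_values("depth_top_cm")
        tops = group["depth_top_cm"].to_numpy(dtype=float)
        bottoms = group["depth_bottom_cm"].to_numpy(dtype=float)
        if not np.allclose(tops[1:], bottoms[:-1]):
            line = int(group.index[0]) + 2
            raise CoreTableError(
                f"non-contiguous depth bins for {species}/{phen}/rep {rep}/loc {loc} (near line {line})"
            )
        if (bottoms <= tops).any():
            line = int(group.index[0]) + 2
            raise CoreTableError(f"non-increasing depth bins near line {line}")
        bins = tuple(tops) + (float(bottoms[-1]),)
        loc_id: int | str = int(loc) if str(loc).isdigit() else str(loc)
        samples.append(
            coring.CoreSample(
                location_id=loc_id,
                replicate_id=int(rep),
                species=str(species),
                phenotype=str(phen),
                depth_bins=bins,
                root_length_by_bin=group["root_length_cm"].to_numpy(dtype=float),
                rld_by_bin=group["rld_cm_cm3"].to_numpy(dtype=float),
            )
        )
    return samples


def samples_to_species_data(samples: Sequence[coring.CoreSample], species: str) -> SpeciesData:
    """Assemble field-style CoreSamples into the per-replicate array layout.

    Only per-location core arrays are populated (no whole-plot truth); the
    reference for subset evaluation must then be "voronoi_all6".
    """
    sel = [s for s in samples if s.species == species]
    if not sel:
        raise ValueError(f"no samples for species {species!r}")
    bins = tuple(sel[0].depth_bins)
    phens = sorted({s.phenotype for s in sel})
    locs = sorted({s.location_id for s in sel}, key=str)
    core_rl: dict[str, dict] = {}
    core_rld: dict[str, dict] = {}
    truth: dict[str, np.ndarray] = {}
    n_bins = len(bins) - 1
    for phen in phens:
        reps = sorted({s.replicate_id for s in sel if s.phenotype == phen})
        rep_index = {r: i for i, r in enumerate(reps)}
        core_rl[phen] = {loc: np.zeros((len(reps), n_bins)) for loc in locs}
        core_rld[phen] = {loc: np.zeros((len(reps), n_bins)) for loc in locs}
        for s in sel:
            if s.phenotype != phen:
                continue
            i = rep_index[s.replicate_id]
            core_rl[phen][s.location_id][i] = s.root_length_by_bin
            core_rld[phen][s.location_id][i] = s.rld_by_bin
        truth[phen] = np.full((len(reps), n_bins), np.nan)
    return SpeciesData(
        species=species,
        layout=layout_mod.default_layout(species),
        depth_bins=bins,
        truth=truth,
        core_rld=core_rld,
        core_rl=core_rl,
        total_root_length={p: np.full(next(iter(core_rl[p].values())).shape[0], np.nan) for p in phens},
    )


# --------------------------------------------------------------------------
# Full study
# --------------------------------------------------------------------------

def run_study(config: StudyConfig) -> dict:
    """Run the complete in-silico study and write all output tables.

    Returns a dict of the in-memory results; every table is also written
    under ``config.outdir`` along with Voronoi weights and a run manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failures: list[str] = []

    species_data: dict[str, SpeciesData] = {}
    for species in config.species:
        logger.info("simulating %s (%d replicates x %d phenotypes)", species, config.n_replicates, len(config.phenotypes))
        species_data[species] = simulate_species(
            species, config.phenotypes, config.n_replicates, config.seed
        )

    results: dict = {"species_data": species_data}

    cores_df = cores_to_dataframe(species_data)
    cores_df.to_csv(outdir / "core_samples.csv", index=False)

    truth_rows = []
    for species, data in species_data.items():
        for phen, arr in data.truth.items():
            for i in range(arr.shape[0]):
                for b in range(arr.shape[1]):
                    truth_rows.append(
                        {
                            "species": species,
                            "phenotype": phen,
                            "replicate": i,
                            "depth_top_cm": data.depth_bins[b],
                            "depth_bottom_cm": data.depth_bins[b + 1],
                            "rld_cm_cm3": arr[i, b],
                        }
                    )
    pd.DataFrame(truth_rows).to_csv(outdir / "whole_plot_profiles.csv", index=False)

    tost_df = tost_equivalence_matrix(species_data, config.tost)
    tost_df.to_csv(outdir / "tost_matrix.csv", index=False)
    results["tost_matrix"] = tost_df
    results["equivalence_counts"] = equivalence_counts(tost_df)

    weights_blob = {}
    for species, data in species_data.items():
        w = layout_mod.voronoi_weights(data.layout, ALL_LOCATIONS)
        weights_blob[species] = json.loads(w.to_json())
    (outdir / "voronoi_weights.json").write_text(json.dumps(weights_blob, indent=2))

    ranking_frames = []
    for species, data in species_data.items():
        for reference in ("whole_plot", "voronoi_all6"):
            for method in ("unadjusted", "voronoi"):
                try:
                    ranking = evaluate_subsets(
                        data, reference=reference, method=method, subset_sizes=config.subset_sizes
                    )
                except Exception as err:  # pragma: no cover - defensive
                    failures.append(f"subset ranking {species}/{reference}/{method}: {err}")
                    logger.error("subset ranking failed: %s", err)
                    continue
                t = ranking.table.copy()
                t.insert(0, "species", species)
                t.insert(1, "reference", reference)
                t.insert(2, "method", method)
                ranking_frames.append(t)
    rankings_df = pd.concat(ranking_frames, ignore_index=True)
    rankings_df.to_csv(outdir / "subset_rankings.csv", index=False)
    results["subset_rankings"] = rankings_df

    metric_frames = [depth_metric_table(data) for data in species_data.values()]
    metrics_df = pd.concat(metric_frames, ignore_index=True)
    metrics_df.to_csv(outdir / "depth_metrics.csv", index=False)
    results["depth_metrics"] = metrics_df

    power_frames = []
    for species, data in species_data.items():
        power_frames.append(
            power_analysis(
                data,
                n_range=config.power_n_range,
                reps=config.power_reps,
                alpha=config.alpha,
                seed=config.seed,
            )
        )
    power_df = pd.concat(power_frames, ignore_index=True)
    power_df.to_csv(outdir / "power_curves.csv", index=False)
    results["power_curves"] = power_df

    qda_frames = []
    max_train = config.n_replicates - config.qda_n_test
    if max_train >= min(config.qda_training_sizes) and max_train > len(coring.DEFAULT_DEPTH_BINS) - 1:
        sizes = tuple(s for s in config.qda_training_sizes if s <= max_train)
        for species, data in species_data.items():
            qda_frames.append(
                qda_tables(
                    data,
                    training_sizes=sizes,
                    n_test=config.qda_n_test,
                    n_draws=config.qda_n_draws,
                    seed=config.seed,
                )
            )
        qda_df = pd.concat(qda_frames, ignore_index=True)
    else:
        # scaled runs without enough replicates for the train/test protocol
        # shrink the test set rather than dropping the analysis
        n_test = max(config.n_replicates // 2, len(coring.DEFAULT_DEPTH_BINS))
        max_train = config.n_replicates - n_test
        sizes = tuple(s for s in config.qda_training_sizes if s <= max_train) or (max_train,)
        if max_train <= len(coring.DEFAULT_DEPTH_BINS) - 1:
            failures.append("QDA skipped: too few replicates for any training size")
            qda_df = pd.DataFrame()
        else:
            for species, data in species_data.items():
                qda_frames.append(
                    qda_tables(
                        data,
                        training_sizes=sizes,
                        n_test=n_test,
                        n_draws=config.qda_n_draws,
                        seed=config.seed,
                    )
                )
            qda_df = pd.concat(qda_frames, ignore_index=True)
    qda_df.to_csv(outdir / "qda_misclassification.csv", index=False)
    results["qda"] = qda_df

    totals_rows = []
    for species, data in species_data.items():
        for phen, tot in data.total_root_length.items():
            for i, v in enumerate(tot):
                totals_rows.append(
                    {"species": species, "phenotype": phen, "replicate": i, "total_root_length_cm": v}
                )
    pd.DataFrame(totals_rows).to_csv(outdir / "total_root_length.csv", index=False)

    manifest = {
        # outdir is excluded so identical runs into different directories
        # produce identical manifests
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("tost", "outdir")},
            "tost": asdict(config.tost),
        },
        "seed": config.seed,
        "failures": failures,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["failures"] = failures
    return results
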