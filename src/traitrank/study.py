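"""End-to-end study orchestration.

One replicate = simulate an F2 population, derive the 11 traits under a
scenario's architecture, split 80/20, fit the requested prediction
methods for PT1 from PT2..PT11, and compute every applicable importance
measure.  A study repeats this over replicates and scenarios and
aggregates R^2 summaries, correlation structure, indirect selection
gains, importance score/rank summaries and rank frequencies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import build_genome_map, simulate_f2
from .traits import (
    TRAIT_HERITABILITY,
    TRAIT_IDS,
    build_architectures,
    simulate_phenotypes,
    realized_heritability,
)
from .models import (
    fit_mlp,
    fit_rbf,
    fit_stepwise,
    fit_tree_ensembles,
    split_train_validation,
)
from .importance import importance_report
from .genetics import (
    SelectionGainInput,
    correlation_edges,
    genetic_correlation,
    indirect_gain,
    pearson_matrix,
    selection_intensity,
)

__all__ = [
    "StudyConfig",
    "validate_config",
    "simulate_replicate",
    "fit_all_methods",
    "run_replicate",
    "run_study",
]

ALL_METHODS = ("stepwise", "mlp", "rbf", "tree", "bagging", "random_forest", "boosting")
PRINCIPAL = "PT1"


@dataclass
class StudyConfig:
    """All knobs of the study, defaulting to the reference design:
    500 F2 individuals, 1,000 markers on 10 groups of 100 cM, the
    11-trait architecture, 80/20 split, 10-fold CV, 5,000 trees."""

    n_individuals: int = 500
    n_groups: int = 10
    markers_per_group: int = 100
    group_length_cm: float = 100.0
    mapping: str = "haldane"
    mu: float = 100.0
    additive_effect: float = 1.0
    dominance_degree: float = 0.5
    heritabilities: dict = field(default_factory=lambda: dict(TRAIT_HERITABILITY))
    shared_weights: bool = True
    scenarios: tuple = (1, 2, 3, 4)
    split_fraction: float = 0.8
    k_folds: int = 10
    compute_cv: bool = False
    methods: tuple = ALL_METHODS
    n_trees: int = 5000
    mlp_hidden_neurons: int = 30
    mlp_max_epochs: int = 5000
    mlp_mse_stop: float = 1e-3
    mlp_alpha: float = 1.0
    rbf_neurons: tuple = tuple(range(10, 31, 2))
    rbf_radii: tuple = tuple(np.arange(5.0, 15.0 + 0.25, 0.5))
    n_perm: int = 10
    selected_fraction: float = 0.40
    n_replicates: int = 50
    seed: int = 0

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


_BOUNDS = {
    "n_individuals": (1, None),
    "n_groups": (1, None),
    "markers_per_group": (10, None),
    "group_length_cm": (0, None),
    "mu": (None, None),
    "additive_effect": (0, None),
    "dominance_degree": (None, None),
    "split_fraction": (0, 1),
    "k_folds": (2, None),
    "n_trees": (1, None),
    "mlp_hidden_neurons": (1, None),
    "mlp_max_epochs": (1, None),
    "mlp_mse_stop": (0, None),
    "mlp_alpha": (0, None),
    "n_perm": (1, None),
    "selected_fraction": (0, 1),
    "n_replicates": (1, None),
}


def validate_config(raw: dict | None) -> tuple[StudyConfig, list[str]]:
    """Build a StudyConfig from a (possibly empty) mapping, collecting
    every violation rather than stopping at the first."""
    raw = dict(raw or {})
    errors: list[str] = []
    cfg = StudyConfig()
    known = set(asdict(cfg))
    for key in sorted(set(raw) - known):
        errors.append(f"{key}: unknown configuration field")
    for key in set(raw) & known:
        value = raw[key]
        if isinstance(value, list):
            value = tuple(value)
        if key == "heritabilities":
            merged = dict(TRAIT_HERITABILITY)
            for trait, h2 in dict(value).items():
                if trait not in TRAIT_HERITABILITY:
                    errors.append(f"heritabilities.{trait}: unknown trait")
                elif not 0 < h2 <= 1:
                    errors.append(f"heritabilities.{trait}: h2 must be in (0, 1], got {h2}")
                else:
                    merged[trait] = float(h2)
            value = merged
        setattr(cfg, key, value)
    for key, (lo, hi) in _BOUNDS.items():
        v = getattr(cfg, key)
        if not isinstance(v, (int, float, np.integer, np.floating)):
            errors.append(f"{key}: expected a number, got {v!r}")
            continue
        strict_low = key in ("split_fraction", "selected_fraction", "group_length_cm",
                             "mlp_mse_stop")
        if lo is not None and (v < lo or (strict_low and v <= lo)):
            errors.append(f"{key}: must be {'>' if strict_low else '>='} {lo}, got {v}")
        if hi is not None and v >= hi:
            errors.append(f"{key}: must be < {hi}, got {v}")
    for s in cfg.scenarios:
        if s not in (1, 2, 3, 4):
            errors.append(f"scenarios: unknown scenario {s}; valid scenarios are [1, 2, 3, 4]")
    for m in cfg.methods:
        if m not in ALL_METHODS:
            errors.append(f"methods: unknown method {m!r}; valid methods are {list(ALL_METHODS)}")
    if cfg.mapping not in ("haldane", "kosambi"):
        errors.append(f"mapping: must be 'haldane' or 'kosambi', got {cfg.mapping!r}")
    return cfg, errors


def replicate_rng(master_seed: int, scenario: int, replicate: int) -> np.random.Generator:
    """Child generator for one replicate: seeded by the (master seed,
    scenario, replicate) triple so any replicate is independently
    reproducible."""
    return np.random.default_rng([master_seed, scenario, replicate])


def simulate_replicate(config: StudyConfig, scenario: int, replicate: int):
    """Genotypes + phenotypes of one replicate under one scenario."""
    rng = replicate_rng(config.seed, scenario, replicate)
    gmap = build_genome_map(config.n_groups, config.markers_per_group, config.group_length_cm)
    genotypes = simulate_f2(gmap, config.n_individuals, rng, config.mapping)
    archs = build_architectures(
        scenario, gmap, rng,
        mu=config.mu,
        additive_effect=config.additive_effect,
        dominance_degree=config.dominance_degree,
        shared_weights=config.shared_weights,
    )
    for tid, h2 in config.heritabilities.items():
        if tid in archs:
            archs[tid].h2 = h2
    table = simulate_phenotypes(genotypes, archs, rng)
    return gmap, genotypes, table


def fit_all_methods(
    phenotypes: pd.DataFrame,
    config: StudyConfig,
    rng: np.random.Generator,
    principal: str = PRINCIPAL,
) -> tuple[dict, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Split the phenotype table and fit every configured method.

    Returns (fits by method, validation X, validation y) plus the split
    itself, so importance measures can reuse the same held-out data.
    """
    aux = [t for t in phenotypes.columns if t != principal]
    X = phenotypes[aux]
    y = phenotypes[principal].to_numpy(float)
    tr, va = split_train_validation(len(y), config.split_fraction, rng)
    X_tr, X_va, y_tr, y_va = X.iloc[tr], X.iloc[va], y[tr], y[va]
    fit_seed = int(rng.integers(2**31))
    cv = config.k_folds if config.compute_cv else None

    fits = {}
    for method in config.methods:
        if method == "stepwise":
            fits[method] = fit_stepwise(X_tr, y_tr, X_va, y_va, cv_folds=cv, cv_seed=fit_seed)
        elif method == "mlp":
            fits[method] = fit_mlp(
                X_tr, y_tr, X_va, y_va,
                hidden_neurons=config.mlp_hidden_neurons,
                max_epochs=config.mlp_max_epochs,
                mse_stop=config.mlp_mse_stop,
                alpha=config.mlp_alpha,
                seed=fit_seed, cv_folds=cv, cv_seed=fit_seed,
            )
        elif method == "rbf":
            fits[method] = fit_rbf(
                X_tr, y_tr, X_va, y_va,
                neurons=config.rbf_neurons, radii=config.rbf_radii,
                seed=fit_seed, cv_folds=cv, cv_seed=fit_seed,
            )
        else:
            fits[method] = fit_tree_ensembles(
                X_tr, y_tr, X_va, y_va, method=method,
                n_trees=config.n_trees, seed=fit_seed, cv_folds=cv, cv_seed=fit_seed,
            )
    return fits, X_va, y_va, va


def run_replicate(config: StudyConfig, scenario: int, replicate: int = 0) -> dict:
    """Simulate, fit every configured method, and measure importance.

    Returns a dict with the phenotype table, per-method FitResults, the
    tidy importance table, the correlation matrix, and indirect gains.
    """
    _, _, table = simulate_replicate(config, scenario, replicate)
    rng = np.random.default_rng([config.seed, scenario, replicate, 1])
    fits, X_va, y_va, _ = fit_all_methods(table.phenotypes, config, rng)
    aux = [t for t in table.trait_ids if t != PRINCIPAL]

    imp = pd.concat(
        [
            importance_report(f, X_va, y_va, config.n_perm, np.random.default_rng(
                [config.seed, scenario, replicate, 2, k]))
            for k, f in enumerate(fits.values())
        ],
        ignore_index=True,
    )
    imp.insert(0, "replicate", replicate)
    imp.insert(0, "scenario", scenario)

    r, pv, flag = pearson_matrix(table)
    i = selection_intensity(config.selected_fraction)
    gains = []
    for t in aux:
        rg = genetic_correlation(table, PRINCIPAL, t, mode="oracle")
        gs, pct = indirect_gain(
            SelectionGainInput(
                i=i,
                h_x=float(np.sqrt(table.architectures[PRINCIPAL].h2)),
                r_g=rg,
                s_gy=float(table.phenotypes[t].std(ddof=1)),
                mu_y=float(table.phenotypes[t].mean()),
            )
        )
        gains.append((scenario, replicate, t, rg, gs, pct))
    gains = pd.DataFrame(
        gains, columns=["scenario", "replicate", "trait", "r_g", "gain", "gain_pct"]
    )

    fit_rows = pd.DataFrame(
        [
            (scenario, replicate, m, f.r2_train, f.r2_validation, f.r2_cv, f.mse_validation)
            for m, f in fits.items()
        ],
        columns=["scenario", "replicate", "method", "r2_train", "r2_validation", "r2_cv",
                 "mse_validation"],
    )
    h2_rows = pd.DataFrame(
        [(scenario, replicate, t, realized_heritability(table, t)) for t in table.trait_ids],
        columns=["scenario", "replicate", "trait", "realized_h2"],
    )
    return {
        "table": table,
        "fits": fits,
        "fit_summary": fit_rows,
        "importance": imp,
        "correlations": r,
        "correlation_flags": flag,
        "edges": correlation_edges(table),
        "gains": gains,
        "heritability": h2_rows,
    }


def aggregate(fit_rows: pd.DataFrame, imp_rows: pd.DataFrame, gain_rows: pd.DataFrame,
              h2_rows: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summaries across replicates: mean/SD R^2 per method x scenario,
    mean importance score and rank, rank frequencies, gains, realized h2."""
    r2_summary = (
        fit_rows.groupby(["scenario", "method"])[["r2_train", "r2_validation", "r2_cv",
                                                  "mse_validation"]]
        .agg(["mean", "std"])
    )
    imp_summary = (
        imp_rows.groupby(["scenario", "method", "measure", "trait"])[["score", "rank"]]
        .mean()
        .rename(columns={"score": "mean_score", "rank": "mean_rank"})
        .reset_index()
    )
    best = imp_rows[imp_rows["rank"] == 1.0]
    n_traits = imp_rows.groupby(["scenario", "method", "measure"])["trait"].nunique()
    worst = imp_rows.join(
        n_traits.rename("n_traits"), on=["scenario", "method", "measure"]
    )
    worst = worst[worst["rank"] == worst["n_traits"]]
    rank_freq = (
        best.groupby(["scenario", "method", "measure", "trait"]).size().rename("n_top")
        .to_frame()
        .join(
            worst.groupby(["scenario", "method", "measure", "trait"]).size().rename("n_bottom"),
            how="outer",
        )
        .fillna(0)
        .astype(int)
        .reset_index()
    )
    gain_summary = (
        gain_rows.groupby(["scenario", "trait"])[["r_g", "gain", "gain_pct"]].mean().reset_index()
    )
    h2_summary = (
        h2_rows.groupby(["scenario", "trait"])["realized_h2"].agg(["mean", "std"]).reset_index()
    )
    return {
        "r2_summary": r2_summary,
        "importance_summary": imp_summary,
        "rank_frequency": rank_freq,
        "gain_summary": gain_summary,
        "heritability_summary": h2_summary,
    }


def run_study(config: StudyConfig, out_dir: str | Path | None = None,
              progress: bool = False) -> dict[str, pd.DataFrame]:
    """Run the full replicated study and (optionally) write all outputs.

    Per-replicate tidy CSVs go under ``out_dir/replicates``; aggregate
    tables and a run log under ``out_dir``.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "replicates").mkdir(parents=True, exist_ok=True)
    fit_rows, imp_rows, gain_rows, h2_rows, edge_rows = [], [], [], [], []
    for scenario in config.scenarios:
        for rep in range(config.n_replicates):
            res = run_replicate(config, scenario, rep)
            fit_rows.append(res["fit_summary"])
            imp_rows.append(res["importance"])
            gain_rows.append(res["gains"])
            h2_rows.append(res["heritability"])
            edges = res["edges"]
            edges.insert(0, "replicate", rep)
            edges.insert(0, "scenario", scenario)
            edge_rows.append(edges)
            if out is not None:
                res["importance"].to_csv(
                    out / "replicates" / f"scenario{scenario}_rep{rep}_importance.csv",
                    index=False,
                )
            if progress:
                print(f"scenario {scenario} replicate {rep}: done")
    fit_rows = pd.concat(fit_rows, ignore_index=True)
    imp_rows = pd.concat(imp_rows, ignore_index=True)
    gain_rows = pd.concat(gain_rows, ignore_index=True)
    h2_rows = pd.concat(h2_rows, ignore_index=True)
    edge_rows = pd.concat(edge_rows, ignore_index=True)
    tables = aggregate(fit_rows, imp_rows, gain_rows, h2_rows)
    tables["fits"] = fit_rows
    tables["importance"] = imp_rows
    tables["gains"] = gain_rows
    tables["heritability"] = h2_rows
    tables["edges"] = edge_rows
    if out is not None:
        for name in ("r2_summary", "importance_summary", "rank_frequency", "gain_summary",
                     "heritability_summary", "fits", "edges"):
            tables[name].to_csv(out / f"{name}.csv")
        (out / "run_log.txt").write_text(
            f"traitrank {__version__}\nseed {config.seed}\n"
            f"config_hash {config.config_hash()}\n"
            f"scenarios {list(config.scenarios)} replicates {config.n_replicates}\n"
        )
    return tables
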