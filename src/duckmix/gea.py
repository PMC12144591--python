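"""Genotype-environment association via allele-frequency turnover forests.

Per locus, a random-forest regression of per-site minor-allele frequency
on the environmental variables yields (a) an out-of-bag R² measuring how
much of the frequency variation the environment explains, and (b) the
impurity reduction of every split, resolved by variable and threshold.
Importances are aggregated across loci weighted by positive out-of-bag R²
and accumulated along each variable's range into a monotone cumulative
turnover curve. Landscapes are analysed by mapping every grid cell's
environment through the top-k curves (a k-dimensional "adaptive" space),
summarizing with PCA/RGB, and measuring genomic offset as the Euclidean
distance between a cell's current and future positions in that space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from duckmix.genofilter import MISSING, GenotypeMatrix

NON_VARIABLE_COLS = ("site_id", "cell_id", "lon", "lat")


def env_variable_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in NON_VARIABLE_COLS]


# ---------------------------------------------------------------------------
# Site allele frequencies
# ---------------------------------------------------------------------------


def site_allele_frequencies(matrix: GenotypeMatrix,
                            min_polymorphic_sites: int = 5,
                            fill: str = "locus_mean") -> pd.DataFrame:
    """Per-site minor-allele frequencies, filtered by site polymorphism.

    The minor allele is defined globally per locus (overall frequency
    <= 0.5). A site counts as polymorphic for a locus when both alleles
    are observed there; loci polymorphic in fewer than
    ``min_polymorphic_sites`` sites are removed (monomorphic loci always
    are). Sites with no genotyped individuals at a locus get NaN, filled
    per ``fill``: ``locus_mean`` (default) or ``keep`` (leave NaN).
    """
    if matrix.metadata is None or "site_id" not in matrix.metadata.columns:
        raise ValueError("individuals must carry a site_id metadata column")
    sites = matrix.metadata["site_id"].to_numpy()
    site_names = sorted(set(sites))
    geno = matrix.genotypes
    obs = geno != MISSING

    global_p = matrix.allele_frequencies()
    minor_is_alt = global_p <= 0.5

    freq = np.full((len(site_names), matrix.n_loci), np.nan)
    poly = np.zeros(matrix.n_loci, dtype=int)
    for s, name in enumerate(site_names):
        rows = sites == name
        ok = obs[rows]
        alt = np.where(ok, geno[rows], 0).sum(axis=0).astype(float)
        tot = 2.0 * ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(tot > 0, alt / tot, np.nan)
        p_minor = np.where(minor_is_alt, p_alt, 1.0 - p_alt)
        freq[s] = p_minor
        poly += ((p_alt > 0) & (p_alt < 1)).astype(int)

    keep = poly >= min_polymorphic_sites
    freq = freq[:, keep]
    loci = [matrix.locus_ids[j] for j in np.flatnonzero(keep)]
    table = pd.DataFrame(freq, index=pd.Index(site_names, name="site_id"),
                         columns=loci)
    if fill == "locus_mean":
        table = table.fillna(table.mean(axis=0))
    elif fill != "keep":
        raise ValueError("fill must be 'locus_mean' or 'keep'")
    return table


# ---------------------------------------------------------------------------
# Turnover model
# ---------------------------------------------------------------------------


@dataclass
class TurnoverModel:
    """Aggregated allele-frequency turnover along environmental gradients.

    ``curves[v]`` is a pair (thresholds, cumulative) defining a
    non-decreasing right-continuous step function whose final value equals
    ``variable_importance[v]``. ``total_weight`` is the sum of positive
    out-of-bag R² over loci (the weight mass behind the model), used when
    combining models.
    """

    variables: list[str]
    per_locus_r2: pd.Series
    variable_importance: pd.Series
    curves: dict[str, tuple[np.ndarray, np.ndarray]]
    training_range: dict[str, tuple[float, float]]
    n_loci_retained: int
    total_weight: float

    def ranking(self) -> list[str]:
        return list(self.variable_importance.sort_values(ascending=False).index)

    def top_variables(self, k: int = 5) -> list[str]:
        return self.ranking()[:k]

    def mean_r2(self) -> float:
        pos = self.per_locus_r2[self.per_locus_r2 > 0]
        return float(pos.mean()) if len(pos) else 0.0

    def curve_value(self, variable: str, x: np.ndarray) -> np.ndarray:
        thr, cum = self.curves[variable]
        if len(thr) == 0:
            return np.zeros(np.shape(x))
        idx = np.searchsorted(thr, x, side="right")
        padded = np.concatenate([[0.0], cum])
        return padded[idx]


def _tree_split_records(est, n_features: int) -> list[tuple[int, float, float]]:
    t = est.tree_
    w = t.weighted_n_node_samples
    total = w[0]
    out = []
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        gain = (w[node] * t.impurity[node] - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]) / total
        if gain > 0:
            out.append((int(t.feature[node]), float(t.threshold[node]), gain))
    return out


def fit_turnover(freqs: pd.DataFrame, env: pd.DataFrame, n_trees: int = 100,
                 seed: int = 0, min_leaf: int = 2,
                 max_features: str | float = "sqrt") -> TurnoverModel:
    """Fit per-locus turnover forests and aggregate importance curves.

    ``freqs``: sites x loci minor-allele frequencies (index site_id);
    ``env``: per-site table with a ``site_id`` column and variable columns.
    Loci with non-positive out-of-bag R² get zero weight. Per retained
    locus, split impurity reductions are normalized to sum to 1 and scaled
    by the locus R²; curves average these over retained loci, so the final
    value of a variable's curve is its R²-weighted importance.
    """
    env = env.set_index("site_id") if "site_id" in env.columns else env
    env = env.loc[freqs.index]
    variables = env_variable_columns(env.reset_index())
    X = env[variables].to_numpy(dtype=float)
    if X.shape[0] < 5:
        raise ValueError("need at least 5 sites")
    if len(variables) < 2:
        raise ValueError("need at least 2 environmental variables")

    rng = np.random.default_rng(seed)
    r2 = {}
    accum: dict[str, list[tuple[float, float]]] = {v: [] for v in variables}
    retained = 0
    for locus in freqs.columns:
        y = freqs[locus].to_numpy(dtype=float)
        if np.nanstd(y) == 0 or np.isnan(y).any():
            r2[locus] = 0.0
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees, oob_score=True, bootstrap=True,
            min_samples_leaf=min_leaf, max_features=max_features,
            random_state=int(rng.integers(2 ** 31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X, y)
            score = float(rf.oob_score_)
        r2[locus] = score
        if score <= 0:
            continue
        retained += 1
        splits: list[tuple[int, float, float]] = []
        for est in rf.estimators_:
            splits.extend(_tree_split_records(est, len(variables)))
        total_gain = sum(g for _, _, g in splits)
        if total_gain <= 0:
            continue
        scale = score / total_gain
        for f, thr, gain in splits:
            accum[variables[f]].append((thr, gain * scale))

    curves = {}
    importance = {}
    denom = max(retained, 1)
    for v in variables:
        if accum[v]:
            pairs = sorted(accum[v])
            thr = np.array([p[0] for p in pairs])
            gains = np.array([p[1] for p in pairs]) / denom
            uthr, inv = np.unique(thr, return_inverse=True)
            binned = np.zeros(len(uthr))
            np.add.at(binned, inv, gains)
            curves[v] = (uthr, np.cumsum(binned))
            importance[v] = float(binned.sum())
        else:
            curves[v] = (np.array([]), np.array([]))
            importance[v] = 0.0

    r2_series = pd.Series(r2, name="oob_r2")
    total_weight = float(r2_series[r2_series > 0].sum())
    return TurnoverModel(
        variables=variables,
        per_locus_r2=r2_series,
        variable_importance=pd.Series(importance).sort_values(ascending=False),
        curves=curves,
        training_range={v: (float(env[v].min()), float(env[v].max()))
                        for v in variables},
        n_loci_retained=retained,
        total_weight=total_weight,
    )


# ---------------------------------------------------------------------------
# Null comparison
# ---------------------------------------------------------------------------


def null_comparison(freqs: pd.DataFrame, env: pd.DataFrame, n_null: int = 100,
                    seed: int = 0, **fit_kwargs) -> dict:
    """Compare the empirical model fit against randomized-environment nulls.

    Site labels of the environment table are permuted ``n_null`` times and
    the model refitted; the comparison metric is the mean out-of-bag R²
    over retained (positive-R²) loci. Returns the empirical value, the
    null distribution, and the fraction of nulls the empirical model
    exceeds.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    env = env.set_index("site_id") if "site_id" in env.columns else env
    env = env.loc[freqs.index]
    rng = np.random.default_rng(seed)
    empirical = fit_turnover(freqs, env.reset_index(), seed=seed, **fit_kwargs)
    null_means = []
    for b in range(n_null):
        perm = rng.permutation(len(env))
        shuffled = env.iloc[perm].copy()
        shuffled.index = env.index
        m = fit_turnover(freqs, shuffled.reset_index(),
                         seed=int(rng.integers(2 ** 31)), **fit_kwargs)
        null_means.append(m.mean_r2())
    null_means = np.array(null_means)
    return {
        "empirical_mean_r2": empirical.mean_r2(),
        "null_mean_r2": null_means,
        "exceedance": float((empirical.mean_r2() > null_means).mean()),
        "model": empirical,
    }


# ---------------------------------------------------------------------------
# Landscape transformation, RGB mapping, offset
# ---------------------------------------------------------------------------


def transform_environment(model: TurnoverModel, grid: pd.DataFrame,
                          top_k: int = 5) -> pd.DataFrame:
    """Map grid-cell environments through the top-k cumulative curves.

    Each output column is the cumulative-importance coordinate of one
    top-ranked variable; values outside the training range clamp to the
    curve endpoints (step functions are flat beyond their last split).
    """
    top = model.top_variables(top_k)
    missing = [v for v in top if v not in grid.columns]
    if missing:
        raise ValueError(f"grid lacks model variable(s): {missing}")
    out = grid[[c for c in ("cell_id", "site_id", "lon", "lat")
                if c in grid.columns]].copy()
    for v in top:
        out[v] = model.curve_value(v, grid[v].to_numpy(dtype=float))
    return out


def _coordinate_columns(transformed: pd.DataFrame) -> list[str]:
    return [c for c in transformed.columns if c not in NON_VARIABLE_COLS]


def map_rgb(transformed: pd.DataFrame) -> pd.DataFrame:
    """PCA of transformed coordinates rescaled to RGB channels.

    The first three principal components are min-max rescaled to
    [0, 255]; rank-deficient inputs yield fewer informative channels, the
    remainder filled with 0. Deterministic: component signs are fixed so
    the largest-magnitude loading is positive.
    """
    coords = transformed[_coordinate_columns(transformed)].to_numpy(dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    centered = coords - coords.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    signs = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = (u * s) * signs
    out = transformed[[c for c in ("cell_id", "site_id", "lon", "lat")
                       if c in transformed.columns]].copy()
    channels = ("R", "G", "B")
    for c_i, ch in enumerate(channels):
        if c_i < scores.shape[1] and s[c_i] > 1e-12:
            col = scores[:, c_i]
            rng_ = col.max() - col.min()
            out[f"PC{c_i + 1}"] = col
            out[ch] = (np.round(255 * (col - col.min()) / rng_).astype(int)
                       if rng_ > 0 else 0)
        else:
            out[f"PC{c_i + 1}"] = 0.0
            out[ch] = 0
    return out


def combine_models(models: list[TurnoverModel]) -> TurnoverModel:
    """Combine turnover models by fit-quality-weighted curve aggregation.

    Models must share their variable set. Each model's curves are averaged
    with weight proportional to its total positive-R² mass; combining a
    model with itself therefore reproduces its curves exactly.
    """
    if not models:
        raise ValueError("no models to combine")
    vars0 = set(models[0].variables)
    for m in models[1:]:
        if not (vars0 & set(m.variables)):
            raise ValueError("models share no variables")
        if set(m.variables) != vars0:
            raise ValueError("models must share the same variable set")
    weights = np.array([max(m.total_weight, 0.0) for m in models])
    if weights.sum() == 0:
        weights = np.ones(len(models))
    weights = weights / weights.sum()

    curves = {}
    importance = {}
    for v in models[0].variables:
        thr_all = np.unique(np.concatenate(
            [m.curves[v][0] for m in models if len(m.curves[v][0])] or [[]]))
        if len(thr_all) == 0:
            curves[v] = (np.array([]), np.array([]))
            importance[v] = 0.0
            continue
        combined = np.zeros(len(thr_all))
        for w, m in zip(weights, models):
            combined += w * m.curve_value(v, thr_all)
        curves[v] = (thr_all, combined)
        importance[v] = float(combined[-1])

    ranges = {}
    for v in models[0].variables:
        los = [m.training_range[v][0] for m in models]
        his = [m.training_range[v][1] for m in models]
        ranges[v] = (min(los), max(his))
    return TurnoverModel(
        variables=list(models[0].variables),
        per_locus_r2=pd.concat([m.per_locus_r2 for m in models]),
        variable_importance=pd.Series(importance).sort_values(ascending=False),
        curves=curves,
        training_range=ranges,
        n_loci_retained=sum(m.n_loci_retained for m in models),
        total_weight=float(sum(m.total_weight for m in models)),
    )


def genomic_offset(model: TurnoverModel, current_grid: pd.DataFrame,
                   future_grid: pd.DataFrame, top_k: int = 5) -> pd.DataFrame:
    """Euclidean distance between current and future transformed coordinates.

    Grids must share cells (matched on ``cell_id`` when present, else row
    order). The offset is nonnegative, zero when future equals current,
    and unaffected by variables outside the top-k set or with zero
    importance.
    """
    key = "cell_id" if "cell_id" in current_grid.columns else None
    if key is not None:
        if key not in future_grid.columns or (
                list(current_grid[key]) != list(future_grid[key])):
            raise ValueError("current and future grids have mismatched cells")
    elif len(current_grid) != len(future_grid):
        raise ValueError("current and future grids have mismatched cells")
    cur = transform_environment(model, current_grid, top_k)
    fut = transform_environment(model, future_grid, top_k)
    cols = _coordinate_columns(cur)
    delta = cur[cols].to_numpy() - fut[cols].to_numpy()
    out = cur[[c for c in ("cell_id", "lon", "lat") if c in cur.columns]].copy()
    out["offset"] = np.sqrt((delta ** 2).sum(axis=1))
    return out
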