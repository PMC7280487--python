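"""Semi-parametric factorial inference for event-rate tables.

Rates of rare events per subject violate both normality and sphericity, so
group comparisons here use the Wald-type statistic (WTS) for factorial
repeated-measures designs: with cell-mean vector mu stacked over the
between-subject groups and within-subject cells, contrast matrix H, and
Shat the block-diagonal empirical covariance of the subject vectors scaled
by group sizes (N * Sigma_i / n_i),

    WTS = N * (H mu)' (H Shat H')^+ (H mu),         df = rank(H).

The asymptotic reference is the central chi-square with rank(H) degrees of
freedom, but at epilepsy-study sample sizes that is anti-conservative, so
p-values are also obtained from a parametric bootstrap: resample Gaussian
data with zero mean and the estimated group covariances (the null), and
report the exceedance fraction with the +1 correction.

The user-facing surface follows the statsmodels model/results idiom:
build a :class:`WaldTypeRM` from a wide per-subject DataFrame, call
``fit()``, and read the effect table off the returned
:class:`WaldTypeRMResults` (``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WTSResult",
    "WaldTypeRM",
    "WaldTypeRMResults",
    "wts",
    "parametric_bootstrap_p",
    "holm_adjust",
    "run_study_designs",
]


# ---------------------------------------------------------------------------
# Core quadratic form
# ---------------------------------------------------------------------------

def _group_moments(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, int]:
    """Stacked cell means and N*blockdiag(Sigma_i/n_i) from per-group data."""
    mus, covs, ns = [], [], []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.ndim != 2 or g.shape[0] < 2:
            raise ValueError("each group needs >= 2 complete subject vectors")
        mus.append(g.mean(axis=0))
        covs.append(np.cov(g, rowvar=False, ddof=1))
        ns.append(g.shape[0])
    N = int(sum(ns))
    d = mus[0].size
    mu = np.concatenate(mus)
    S = np.zeros((len(groups) * d, len(groups) * d))
    for i, (c, n) in enumerate(zip(covs, ns)):
        c = np.atleast_2d(c)
        S[i * d : (i + 1) * d, i * d : (i + 1) * d] = N * c / n
    return mu, S, N


def _wts_quadratic(mu: np.ndarray, S: np.ndarray, N: int,
                   H: np.ndarray) -> tuple[float, int]:
    Hmu = H @ mu
    M = H @ S @ H.T
    stat = float(N * Hmu @ np.linalg.pinv(M) @ Hmu)
    df = int(np.linalg.matrix_rank(H))
    return max(stat, 0.0), df


@dataclass
class WTSResult:
    """One effect's Wald-type test."""

    effect: str
    statistic: float
    df: int
    p_asymptotic: float
    p_bootstrap: float | None = None
    n_boot: int = 0

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("rank-0 contrast")


def wts(groups: list[np.ndarray], H: np.ndarray,
        effect: str = "effect") -> WTSResult:
    """Wald-type statistic of contrast ``H`` on per-group subject matrices.

    ``groups[i]`` has shape (n_i, d): one row per subject, one column per
    within-subject cell.  The asymptotic p-value is the upper chi-square
    tail at ``rank(H)`` degrees of freedom.
    """
    from scipy.stats import chi2

    H = np.atleast_2d(np.asarray(H, dtype=float))
    if np.linalg.matrix_rank(H) == 0:
        raise ValueError("rank-0 contrast")
    mu, S, N = _group_moments(groups)
    if H.shape[1] != mu.size:
        raise ValueError(
            f"contrast has {H.shape[1]} columns for a {mu.size}-cell mean vector"
        )
    stat, df = _wts_quadratic(mu, S, N, H)
    return WTSResult(effect, stat, df, float(chi2.sf(stat, df)))


def _nearest_psd(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh((c + c.T) / 2)
    if w.min() >= 0:
        return c
    warnings.warn("covariance repaired to nearest PSD", stacklevel=3)
    w = np.clip(w, 0, None)
    return v @ np.diag(w) @ v.T


def parametric_bootstrap_p(
    groups: list[np.ndarray],
    H: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    observed: float | None = None,
) -> float:
    """Parametric-bootstrap p-value of the WTS.

    Bootstrap datasets are multivariate normal with zero mean and the
    group-wise estimated covariances (the null imposed); the p-value is
    ``(1 + #{WTS* >= WTS_obs}) / (n_boot + 1)``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    H = np.atleast_2d(np.asarray(H, dtype=float))
    mu, S, N = _group_moments(groups)
    if observed is None:
        observed, _ = _wts_quadratic(mu, S, N, H)

    ns = [g.shape[0] for g in groups]
    d = groups[0].shape[1]
    chols = []
    for g in groups:
        c = _nearest_psd(np.atleast_2d(np.cov(g, rowvar=False, ddof=1)))
        # eigen square root handles the semi-definite case
        w, v = np.linalg.eigh(c)
        chols.append(v @ np.diag(np.sqrt(np.clip(w, 0, None))))

    exceed = 0
    # pre-draw everything for speed and reproducibility
    draws = [rng.standard_normal((n_boot, n, d)) for n in ns]
    for b in range(n_boot):
        boot = [draws[i][b] @ chols[i].T for i in range(len(groups))]
        mu_b, S_b, _ = _group_moments(boot)
        stat_b, _ = _wts_quadratic(mu_b, S_b, N, H)
        if stat_b >= observed:
            exceed += 1
    return (1 + exceed) / (n_boot + 1)


def holm_adjust(
    p_values: list[float], alpha: float = 0.05
) -> list[tuple[float, bool]]:
    """Step-down Holm adjustment; returns (p_adjusted, reject) per input.

    ``p_adj(i) = max_{j<=i} min(1, (m-j+1) * p_(j))`` over the ascending
    order, rejection while ``p_adj <= alpha``.
    """
    m = len(p_values)
    if m == 0:
        return []
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return [(float(a), bool(a <= alpha)) for a in adj]


# ---------------------------------------------------------------------------
# Contrast construction
# ---------------------------------------------------------------------------

def _centering(k: int) -> np.ndarray:
    return np.eye(k) - np.ones((k, k)) / k


def _mean_row(k: int) -> np.ndarray:
    return np.ones((1, k)) / k


def factorial_contrast(levels: list[int], involved: list[bool]) -> np.ndarray:
    """Kronecker contrast for a main effect or interaction.

    ``levels`` are the factor level counts in stacking order (between
    factor first, then within factors); ``involved[j]`` marks the factors
    the effect spans.  Involved factors contribute a centering matrix,
    the rest their mean row.
    """
    H = np.ones((1, 1))
    for k, inv in zip(levels, involved):
        H = np.kron(H, _centering(k) if inv else _mean_row(k))
    return H


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

class WaldTypeRM:
    """Wald-type factorial repeated-measures model on a wide DataFrame.

    Parameters
    ----------
    data : DataFrame
        One row per subject.  ``cell_columns`` are the within-subject
        responses (stacked in C order over the within factors);
        ``between`` optionally names the grouping column.
    within : list of (name, n_levels)
        Within-subject factor structure; the product of level counts must
        equal ``len(cell_columns)``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        cell_columns: list[str],
        within: list[tuple[str, int]],
        between: str | None = None,
        between_name: str = "Group",
    ) -> None:
        d = int(np.prod([k for _, k in within]))
        if d != len(cell_columns):
            raise ValueError("within-level product must match cell columns")
        if data[cell_columns].isna().any().any():
            bad = data.loc[
                data[cell_columns].isna().any(axis=1)
            ].index.tolist()
            raise ValueError(f"incomplete within-cell vectors for rows {bad}")
        self.within = list(within)
        self.between = between
        self.between_name = between_name
        if between is None:
            self.group_levels = ["all"]
            self.groups = [data[cell_columns].to_numpy(float)]
        else:
            self.group_levels = sorted(data[between].unique().tolist())
            self.groups = [
                data.loc[data[between] == g, cell_columns].to_numpy(float)
                for g in self.group_levels
            ]
        for g, lev in zip(self.groups, self.group_levels):
            if g.shape[0] < 2:
                raise ValueError(
                    f"group {lev!r} has fewer than 2 subjects"
                )
        self.cell_columns = list(cell_columns)

    # -- effects ----------------------------------------------------------
    def _factor_names(self) -> list[str]:
        names = [] if self.between is None else [self.between_name]
        return names + [n for n, _ in self.within]

    def _levels(self) -> list[int]:
        lev = [] if self.between is None else [len(self.group_levels)]
        return lev + [k for _, k in self.within]

    def effect_contrast(self, effect: str) -> np.ndarray:
        """Contrast matrix for an effect such as ``"A"`` or ``"A:B"``."""
        names = self._factor_names()
        parts = effect.split(":")
        unknown = set(parts) - set(names)
        if unknown:
            raise ValueError(f"unknown factors {sorted(unknown)} in {effect!r}")
        involved = [n in parts for n in names]
        return factorial_contrast(self._levels(), involved)

    def default_effects(self) -> list[str]:
        names = self._factor_names()
        effects = list(names)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                effects.append(f"{names[i]}:{names[j]}")
        return effects

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        effects: list[str] | None = None,
        n_boot: int = 1000,
        seed: int | np.random.Generator = 0,
        alpha: float = 0.05,
    ) -> "WaldTypeRMResults":
        """Test the requested effects (defaults: all mains + pairwise
        interactions), with bootstrap p-values and Holm adjustment across
        the family."""
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        effects = effects or self.default_effects()
        results = []
        for eff in effects:
            H = self.effect_contrast(eff)
            res = wts(self.groups, H, effect=eff)
            if n_boot:
                res.p_bootstrap = parametric_bootstrap_p(
                    self.groups, H, n_boot=n_boot, seed=rng,
                    observed=res.statistic,
                )
                res.n_boot = n_boot
            results.append(res)
        return WaldTypeRMResults(self, results, alpha=alpha)


class WaldTypeRMResults:
    """Fitted effect table with Holm-adjusted decisions."""

    def __init__(self, model: WaldTypeRM, results: list[WTSResult],
                 alpha: float = 0.05) -> None:
        self.model = model
        self.results = results
        self.alpha = alpha
        ps = [r.p_bootstrap if r.p_bootstrap is not None else r.p_asymptotic
              for r in results]
        self.holm = holm_adjust(ps, alpha=alpha)

    def table(self) -> pd.DataFrame:
        rows = []
        for r, (p_adj, rej) in zip(self.results, self.holm):
            rows.append(
                {
                    "effect": r.effect,
                    "WTS": r.statistic,
                    "df": r.df,
                    "p_asymptotic": r.p_asymptotic,
                    "p_bootstrap": r.p_bootstrap,
                    "p_holm": p_adj,
                    "reject": rej,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        t = self.table()
        lines = [
            "Wald-type statistics (parametric bootstrap, "
            f"alpha={self.alpha}, Holm-adjusted)",
            t.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def __getitem__(self, effect: str) -> WTSResult:
        for r in self.results:
            if r.effect == effect:
                return r
        raise KeyError(effect)

    def plot_cell_means(self, ax=None):
        """Group-wise cell means with +/-1 SE bars, one line per group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        m = self.model
        x = np.arange(len(m.cell_columns))
        for lev, g in zip(m.group_levels, m.groups):
            mean = g.mean(axis=0)
            se = g.std(axis=0, ddof=1) / np.sqrt(g.shape[0])
            ax.errorbar(x, mean, yerr=se, marker="o", capsize=3, label=lev)
        ax.set_xticks(x, m.cell_columns)
        ax.set_ylabel("mean rate")
        ax.legend(frameon=False, title=m.between_name if m.between else None)
        return ax


# ---------------------------------------------------------------------------
# The study's factorial designs on a rate table
# ---------------------------------------------------------------------------

def _pivot_rates(rate_table: pd.DataFrame, hemisphere: bool) -> pd.DataFrame:
    sel = rate_table[
        rate_table["hemisphere_or_all"].isin(
            ["left", "right"] if hemisphere else ["all"]
        )
    ]
    if hemisphere:
        wide = sel[sel["hfo_type"] == "all"].pivot_table(
            index="subject_id", columns="hemisphere_or_all",
            values="rate_per_min",
        )[["left", "right"]]
    else:
        wide = sel[sel["hfo_type"] != "all"].pivot_table(
            index="subject_id", columns="hfo_type", values="rate_per_min"
        )[["ripple", "fast_ripple"]]
    return wide.reset_index()


def run_study_designs(
    rate_table: pd.DataFrame,
    groups: dict[str, dict[str, str]],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, WaldTypeRMResults]:
    """Run the study-style factorial analyses on a multi-subject rate table.

    ``groups`` maps subject_id to metadata: ``diagnosis`` (epilepsy /
    control) and optionally ``focus`` (left / right / bilateral / control,
    or ``undefined`` to be excluded).  Two sleep designs are fitted when
    the table carries the corresponding rows: diagnosis x HFO type on
    overall-ROI rates, and focus x hemisphere on hemisphere rates.  Each
    family is Holm-adjusted internally.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, WaldTypeRMResults] = {}

    wide = _pivot_rates(rate_table, hemisphere=False)
    if len(wide):
        wide["diagnosis"] = wide["subject_id"].map(
            lambda s: groups[s]["diagnosis"]
        )
        model = WaldTypeRM(
            wide, ["ripple", "fast_ripple"],
            within=[("HFOType", 2)], between="diagnosis",
            between_name="Epilepsy",
        )
        out["epilepsy_by_hfo_type"] = model.fit(
            n_boot=n_boot, seed=rng, alpha=alpha
        )

    if (rate_table["hemisphere_or_all"].isin(["left", "right"])).any():
        hemi = _pivot_rates(rate_table, hemisphere=True)
        hemi["focus"] = hemi["subject_id"].map(
            lambda s: groups[s].get("focus", "undefined")
        )
        hemi = hemi[hemi["focus"] != "undefined"]
        counts = hemi["focus"].value_counts()
        if len(counts) >= 2 and (counts >= 2).all():
            model = WaldTypeRM(
                hemi, ["left", "right"],
                within=[("ROIHemisphere", 2)], between="focus",
                between_name="EpilepticFocus",
            )
            out["focus_by_hemisphere"] = model.fit(
                n_boot=n_boot, seed=rng, alpha=alpha
            )
    return out
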