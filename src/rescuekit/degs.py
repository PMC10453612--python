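"""Differential expression, drug core gene groups, and overlap permutation tests.

The DE caller is a self-contained negative-binomial test: median-of-ratios
size factors, per-gene method-of-moments dispersion stabilised by a parametric
mean-dispersion trend, and — by default — a likelihood-ratio test comparing
per-group NB means against a common mean at fixed dispersion.  The LRT is
preferred over the delta-method Wald statistic (also provided) because with
three replicates per arm the Wald normal approximation understates far-tail
p-values, which matters when 2000 genes are screened at once.  Genes are
called differential when the Benjamini-Hochberg adjusted p-value is below
``alpha`` AND |log2FC| exceeds ``lfc_threshold`` (defaults 0.05 and 1).

A drug's *core gene group* is the set of genes differential under the drug
alone that become non-differential when a rescuing modulator (serum or a
growth factor) is co-applied; the *restored fraction* is the share of drug
DEGs so rescued.  Overlap significance between DEG sets is assessed with a
permutation null: equally sized sets are drawn uniformly from each gene
universe and the intersection size recorded; the p-value is the fraction of
null intersections at least as large as the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalisation factors per sample.

    The reference is the per-gene geometric mean over samples, computed on
    genes expressed in every sample; each sample's factor is the median of its
    count/reference ratios.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise InsufficientDataError("no gene is expressed in every sample; "
                                    "cannot compute size factors")
    logref = np.log(mat[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(mat[positive]) - logref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_loglik(k, mu, size):
    """NB log-likelihood with var = mu + mu^2/size, elementwise."""
    return (gammaln(k + size) - gammaln(size) - gammaln(k + 1)
            + size * np.log(size / (size + mu))
            + k * np.log(mu / (size + mu) + 1e-300))


def _nb_fit_mean(k, sf, size, max_iter=30):
    """Per-gene NB MLE of the size-factor-adjusted mean (Newton on log q).

    ``k`` is genes x samples raw counts, ``sf`` the per-sample size factors,
    ``size`` the per-gene NB size (1/dispersion); the fitted model is
    ``k_gj ~ NB(q_g * sf_j, size_g)``.
    """
    q = np.maximum(k.mean(axis=1) / sf.mean(), 1e-8)
    for _ in range(max_iter):
        mu = q[:, None] * sf[None, :]
        w = size[:, None] / (size[:, None] + mu)
        score = ((k - mu) * w).sum(axis=1)
        info = (mu * w).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -2.0, 2.0)
        q *= np.exp(step)
        if np.max(np.abs(step)) < 1e-12:
            break
    return q


class NBDifferentialExpression(BaseEstimator):
    """Negative-binomial differential-expression test for one contrast.

    Parameters
    ----------
    alpha : float
        BH-adjusted significance cutoff (default 0.05).
    lfc_threshold : float
        |log2 fold change| required to call a DEG (default 1.0).
    test : {"lrt", "wald"}
        ``"lrt"`` (default): likelihood-ratio test of per-group NB means vs a
        common mean at fixed dispersion, referred to chi-squared with 1 df.
        ``"wald"``: delta-method z statistic on the log fold change, referred
        to the normal distribution; slightly anti-conservative in the extreme
        tail with few replicates.
    min_total_count : int
        Genes with fewer total counts across the contrasted samples are
        excluded before testing (default 10), with the count logged.
    dispersion_floor : float
        Lower bound on the per-gene dispersion estimate (default 0.01).
    dispersion_trend : bool
        With the default True, a parametric mean-dispersion trend
        ``a0 + a1/mu`` is fitted across genes and each gene's dispersion is
        the elementwise maximum of its own method-of-moments estimate and the
        trend, never understating variability relative to the ensemble.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-gene table over the full input universe: ``base_mean``,
        ``log2fc``, ``se_log2fc``, ``stat``, ``pvalue``, ``padj``,
        ``is_deg``, ``direction`` (filtered genes carry NaN statistics and
        ``is_deg = False``).
    size_factors_ : pandas.Series
    dispersion_ : pandas.Series
    n_filtered_ : int
    """

    def __init__(self, alpha: float = 0.05, lfc_threshold: float = 1.0,
                 test: str = "lrt", min_total_count: int = 10,
                 dispersion_floor: float = 0.01,
                 dispersion_trend: bool = True):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.test = test
        self.min_total_count = min_total_count
        self.dispersion_floor = dispersion_floor
        self.dispersion_trend = dispersion_trend

    def fit(self, counts: pd.DataFrame, design: pd.DataFrame,
            contrast: tuple[str, str] = ("drug", "control")):
        """Test `contrast[0]` against the reference `contrast[1]`."""
        cond, ref = contrast
        if (counts.to_numpy() < 0).any():
            raise ParameterError("counts must be non-negative")
        cond_samples = design.index[design["condition"] == cond]
        ref_samples = design.index[design["condition"] == ref]
        if len(cond_samples) < 2 or len(ref_samples) < 2:
            raise InsufficientDataError(
                f"need >= 2 replicates per condition, got {len(cond_samples)} "
                f"({cond}) and {len(ref_samples)} ({ref})")
        missing = set(cond_samples) | set(ref_samples) - set(counts.columns)
        if not set(cond_samples).issubset(counts.columns) or \
                not set(ref_samples).issubset(counts.columns):
            raise ParameterError(f"design samples missing from counts: {missing}")

        sub = counts[list(ref_samples) + list(cond_samples)]
        keep = sub.sum(axis=1) >= self.min_total_count
        self.n_filtered_ = int((~keep).sum())
        if self.n_filtered_:
            logger.info("expression filter: excluded %d gene(s) with total "
                        "count < %d", self.n_filtered_, self.min_total_count)
        expr = sub.loc[keep]

        sf = size_factors(expr)
        self.size_factors_ = sf
        norm = expr / sf

        a = norm[list(ref_samples)].to_numpy()
        b = norm[list(cond_samples)].to_numpy()
        na, nb = a.shape[1], b.shape[1]
        mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)

        # method-of-moments dispersion from pooled within-group variability,
        # on the normalised scale: Var ~= mu/s + alpha*mu^2
        inv_sf_a = float(np.mean(1.0 / sf[list(ref_samples)]))
        inv_sf_b = float(np.mean(1.0 / sf[list(cond_samples)]))
        var_a = a.var(axis=1, ddof=1)
        var_b = b.var(axis=1, ddof=1)
        pooled_var = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        pooled_mu = (na * mu_a + nb * mu_b) / (na + nb)
        inv_sf = (na * inv_sf_a + nb * inv_sf_b) / (na + nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = (pooled_var - pooled_mu * inv_sf) / pooled_mu ** 2
        disp = np.clip(np.nan_to_num(disp), self.dispersion_floor, None)
        if self.dispersion_trend and len(disp) >= 10:
            # parametric trend a0 + a1/mu, least squares on the raw estimates
            design_mat = np.column_stack(
                [np.ones_like(pooled_mu), 1.0 / np.maximum(pooled_mu, 1e-8)])
            coef, *_ = np.linalg.lstsq(design_mat, disp, rcond=None)
            trend = np.maximum(design_mat @ np.maximum(coef, 0.0),
                               self.dispersion_floor)
            disp = np.maximum(disp, trend)
        self.dispersion_ = pd.Series(disp, index=expr.index, name="dispersion")

        eps = 1e-8
        # delta-method standard error of the log2 ratio of group means
        var_mean_a = (mu_a * inv_sf_a + disp * mu_a ** 2) / na
        var_mean_b = (mu_b * inv_sf_b + disp * mu_b ** 2) / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            se_log = np.sqrt(var_mean_a / np.maximum(mu_a, eps) ** 2
                             + var_mean_b / np.maximum(mu_b, eps) ** 2)
        se_log2 = se_log / np.log(2.0)

        if self.test == "lrt":
            size = 1.0 / disp
            k_a = expr[list(ref_samples)].to_numpy(float)
            k_b = expr[list(cond_samples)].to_numpy(float)
            sf_a = sf[list(ref_samples)].to_numpy()
            sf_b = sf[list(cond_samples)].to_numpy()
            q_a = _nb_fit_mean(k_a, sf_a, size)
            q_b = _nb_fit_mean(k_b, sf_b, size)
            q_0 = _nb_fit_mean(np.hstack([k_a, k_b]),
                               np.hstack([sf_a, sf_b]), size)
            ll1 = (_nb_loglik(k_a, q_a[:, None] * sf_a[None, :],
                              size[:, None]).sum(axis=1)
                   + _nb_loglik(k_b, q_b[:, None] * sf_b[None, :],
                                size[:, None]).sum(axis=1))
            mu_0 = q_0[:, None] * np.hstack([sf_a, sf_b])[None, :]
            ll0 = _nb_loglik(np.hstack([k_a, k_b]), mu_0,
                             size[:, None]).sum(axis=1)
            log2fc = np.log2((q_b + eps) / (q_a + eps))
            stat = np.sign(log2fc) * np.sqrt(np.maximum(2.0 * (ll1 - ll0),
                                                        0.0))
            pvalue = stats.chi2.sf(stat ** 2, df=1)
        elif self.test == "wald":
            log2fc = np.log2((mu_b + eps) / (mu_a + eps))
            ok = se_log2 > 0
            stat = np.zeros_like(log2fc)
            stat[ok] = log2fc[ok] / se_log2[ok]
            pvalue = 2.0 * stats.norm.sf(np.abs(stat))
        else:
            raise ParameterError(f"unknown test {self.test!r}")
        padj = bh_adjust(pvalue)

        res = pd.DataFrame({
            "base_mean": pooled_mu, "log2fc": log2fc, "se_log2fc": se_log2,
            "stat": stat, "pvalue": pvalue, "padj": padj,
        }, index=expr.index)
        res["is_deg"] = (res["padj"] < self.alpha) & \
            (res["log2fc"].abs() > self.lfc_threshold)
        res["direction"] = np.where(~res["is_deg"], "none",
                                    np.where(res["log2fc"] > 0, "up", "down"))
        full = res.reindex(counts.index)
        full["is_deg"] = full["is_deg"].astype("boolean").fillna(False).astype(bool)
        full["direction"] = full["direction"].fillna("none")
        self.results_ = full
        self.contrast_ = (cond, ref)
        return self


def call_degs(counts: pd.DataFrame, design: pd.DataFrame,
              contrast: tuple[str, str], alpha: float = 0.05,
              lfc_threshold: float = 1.0, min_total_count: int = 10,
              **kwargs) -> pd.DataFrame:
    """Run the NB differential-expression test; returns the per-gene table."""
    model = NBDifferentialExpression(alpha=alpha, lfc_threshold=lfc_threshold,
                                     min_total_count=min_total_count, **kwargs)
    return model.fit(counts, design, contrast).results_


@dataclass(frozen=True)
class CoreGeneSet:
    """Drug DEGs that become non-differential under a rescuing modulator."""

    drug: str
    modulator: str
    members: dict = field(default_factory=dict)  # gene -> direction under drug
    n_drug_degs: int = 0

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.members.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.members.values() if d == "down")

    @property
    def restored_fraction_pct(self) -> float:
        """Percent of drug DEGs restored to non-differential status."""
        if self.n_drug_degs == 0:
            return float("nan")
        return 100.0 * len(self.members) / self.n_drug_degs


def core_gene_set(deg_drug: pd.DataFrame, deg_drug_plus_mod: pd.DataFrame,
                  drug: str = "drug", modulator: str = "modulator") -> CoreGeneSet:
    """Genes differential under drug alone but not under drug + modulator."""
    if not deg_drug.index.equals(deg_drug_plus_mod.index):
        if set(deg_drug.index) != set(deg_drug_plus_mod.index):
            raise ParameterError("DEG tables come from different gene universes")
        deg_drug_plus_mod = deg_drug_plus_mod.reindex(deg_drug.index)
    drug_degs = deg_drug.index[deg_drug["is_deg"]]
    combo_degs = set(deg_drug_plus_mod.index[deg_drug_plus_mod["is_deg"]])
    members = {g: deg_drug.loc[g, "direction"]
               for g in drug_degs if g not in combo_degs}
    return CoreGeneSet(drug=drug, modulator=modulator, members=members,
                       n_drug_degs=int(len(drug_degs)))


@dataclass(frozen=True)
class OverlapTest:
    """Permutation test of k-set intersection size against a uniform null."""

    observed: int
    n_iterations: int
    p_value: float
    null_samples: np.ndarray = field(repr=False, compare=False, default=None)
    seed: int | None = None

    @property
    def p_annotation(self) -> str:
        if self.p_value == 0.0:
            return f"< {1.0 / self.n_iterations:g}"
        return f"= {self.p_value:g}"


def permutation_overlap_test(sets, universes, n_iter: int = 1000,
                             seed: int = 0,
                             observed: int | None = None) -> OverlapTest:
    """Significance of the common-gene count between 2 or 3 gene sets.

    Each iteration draws, for every set, an equally sized uniform sample
    without replacement from that set's universe, and records the size of the
    intersection of the draws.  The p-value is the fraction of null
    intersection sizes greater than or equal to the observed intersection
    (no +1 correction; a zero is annotated as below 1/n_iter).
    """
    if len(sets) not in (2, 3):
        raise ParameterError("overlap test is defined for 2 or 3 sets")
    if len(universes) != len(sets):
        raise ParameterError("one universe required per set")
    sets = [set(s) for s in sets]
    universes = [np.asarray(list(u)) for u in universes]
    for s, u in zip(sets, universes):
        if not s.issubset(set(u.tolist())):
            raise ParameterError("each set must be a subset of its universe")
    if observed is None:
        observed = len(set.intersection(*sets))
    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in sets]
    null = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        draws = [set(rng.choice(u, size=k, replace=False).tolist())
                 for u, k in zip(universes, sizes)]
        null[it] = len(set.intersection(*draws))
    p = float(np.mean(null >= observed))
    return OverlapTest(observed=int(observed), n_iterations=n_iter,
                       p_value=p, null_samples=null, seed=seed)


def deg_overlap_summary(deg_a: pd.DataFrame, deg_b: pd.DataFrame,
                        n_iter: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Directional DEG overlap between two contrasts with permutation p-values.

    For each direction, reports |A intersect B| / |A| as a percentage together
    with the permutation p-value of the intersection; universes are the genes
    with a defined test result (those passing the expression filter) in each
    table.
    """
    rows = []
    universe_a = deg_a.index[deg_a["pvalue"].notna()]
    universe_b = deg_b.index[deg_b["pvalue"].notna()]
    for direction in ("up", "down"):
        a = set(deg_a.index[deg_a["direction"] == direction])
        b = set(deg_b.index[deg_b["direction"] == direction])
        inter = len(a & b)
        pct = 100.0 * inter / len(a) if a else float("nan")
        if a and b:
            test = permutation_overlap_test([a, b], [universe_a, universe_b],
                                            n_iter=n_iter, seed=seed)
            p = test.p_value
        else:
            p = float("nan")
        rows.append({"direction": direction, "n_a": len(a), "n_b": len(b),
                     "overlap": inter, "pct_of_a": pct, "p_value": p})
    return pd.DataFrame(rows)
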