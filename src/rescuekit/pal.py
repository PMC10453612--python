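"""Pathway activation level (PAL) scoring.

Expression profiles are first normalised gene-wise to case-to-normal ratios
(CNR): each sample's value divided by the geometric mean of that gene across
all samples in the dataset.  A pathway is a set of member genes with
activator/repressor role weights (ARR; positive = activator, negative =
repressor, zero = neutral, magnitude <= 1).  Its activation level in a sample
is the weighted mean of signed log-ratios,

    PAL = K * sum_g ARR_g * log10(CNR_g) / sum_g |ARR_g|

over members present in the profile, with K = 100 by convention.  PAL is 0
when every member sits at its dataset-average expression, positive when
activators are up / repressors down, and negative in the opposite case.
Pathways with fewer than ``min_genes`` (default 10) scored members are
ineligible and skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .degs import bh_adjust
from .exceptions import IneligiblePathwayError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 10


@dataclass(frozen=True)
class Pathway:
    """Named gene set with activator/repressor role weights."""

    name: str
    members: dict = field(default_factory=dict)  # gene -> ARR weight in [-1, 1]

    def __post_init__(self):
        if not any(w != 0 for w in self.members.values()):
            raise ParameterError(
                f"pathway {self.name!r} has no member with a nonzero weight")
        if any(abs(w) > 1 for w in self.members.values()):
            raise ParameterError("ARR weights must have magnitude <= 1")

    def __len__(self) -> int:
        return len(self.members)


def read_gmt(path, weighted: str | bool = "auto") -> list[Pathway]:
    """Parse a GMT gene-set file, optionally with ``gene|weight`` members.

    Standard GMT lines are ``name<TAB>description<TAB>gene...``; in the
    weighted dialect each gene token may carry an ARR weight after a ``|``
    (e.g. ``MAPK1|1`` or ``DUSP6|-1``).  With ``weighted='auto'`` the dialect
    is detected per token; ``weighted=False`` forces all weights to +1.
    """
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParameterError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, tokens = parts[0], parts[1], parts[2:]
            members = {}
            for tok in tokens:
                if not tok:
                    continue
                if weighted is not False and "|" in tok:
                    gene, w = tok.rsplit("|", 1)
                    members[gene] = float(w)
                else:
                    members[tok] = 1.0
            pathways.append(Pathway(name=name, members=members))
    return pathways


def write_gmt(pathways, path) -> None:
    """Write pathways in the weighted GMT dialect (``gene|weight`` tokens)."""
    with open(path, "w") as fh:
        for pw in pathways:
            tokens = [f"{g}|{w:g}" for g, w in pw.members.items()]
            fh.write("\t".join([pw.name, "na"] + tokens) + "\n")


def geometric_mean_normalize(expr: pd.DataFrame,
                             pseudocount: float = 1.0) -> pd.DataFrame:
    """Case-to-normal ratios: each gene divided by its geometric mean.

    Genes that are zero in every sample are excluded; genes with some zeros
    get ``pseudocount`` added across the whole row before normalisation (the
    count of such genes is logged).  The CNR of a gene positive in all
    samples is exact (no pseudocount applied).
    """
    mat = expr.astype(float)
    if (mat.to_numpy() < 0).any():
        raise ParameterError("expression values must be non-negative")
    all_zero = (mat == 0).all(axis=1)
    if all_zero.any():
        logger.info("CNR: excluded %d gene(s) with zero expression in every "
                    "sample", int(all_zero.sum()))
        mat = mat.loc[~all_zero]
    some_zero = (mat == 0).any(axis=1)
    if some_zero.any():
        logger.info("CNR: added pseudocount %g to %d gene(s) with zeros",
                    pseudocount, int(some_zero.sum()))
        mat.loc[some_zero] += pseudocount
    loggm = np.log(mat).mean(axis=1)
    cnr = mat.div(np.exp(loggm), axis=0)
    return cnr


@dataclass(frozen=True)
class PALResult:
    """Activation level of one pathway in one profile."""

    pathway: str
    pal: float
    n_members_used: int
    contributions: pd.Series = field(repr=False, compare=False, default=None)


def pal(pathway: Pathway, profile: pd.Series, k: float = 100.0,
        log_base: float = 10.0,
        min_genes: int = DEFAULT_MIN_GENES) -> PALResult:
    """Pathway activation level of one CNR profile.

    ``profile`` maps gene ids to CNR values (> 0).  Raises
    :class:`IneligiblePathwayError` when fewer than ``min_genes`` members are
    present in the profile.
    """
    present = [g for g in pathway.members if g in profile.index]
    if len(present) < min_genes:
        raise IneligiblePathwayError(
            f"pathway {pathway.name!r}: {len(present)} members present, "
            f"minimum is {min_genes}")
    cnr = profile.loc[present].astype(float)
    if (cnr <= 0).any():
        raise ParameterError("CNR values must be positive")
    arr = np.array([pathway.members[g] for g in present], dtype=float)
    logs = np.log(cnr.to_numpy()) / np.log(log_base)
    denom = np.abs(arr).sum()
    contrib = pd.Series(k * arr * logs / denom, index=present)
    return PALResult(pathway=pathway.name, pal=float(contrib.sum()),
                     n_members_used=len(present), contributions=contrib)


def score_pathways(pathways, cnr: pd.DataFrame, k: float = 100.0,
                   log_base: float = 10.0,
                   min_genes: int = DEFAULT_MIN_GENES) -> pd.DataFrame:
    """PAL of every eligible pathway in every sample (pathways x samples).

    Ineligible pathways (< ``min_genes`` members present) are skipped with a
    log message.
    """
    rows, names = [], []
    for pw in pathways:
        try:
            vals = [pal(pw, cnr[c], k=k, log_base=log_base,
                        min_genes=min_genes).pal for c in cnr.columns]
        except IneligiblePathwayError as exc:
            logger.info("skipped: %s", exc)
            continue
        rows.append(vals)
        names.append(pw.name)
    return pd.DataFrame(rows, index=pd.Index(names, name="pathway"),
                        columns=cnr.columns)


def compare_pal_groups(pal_matrix: pd.DataFrame, labels,
                       group_a: str, group_b: str) -> pd.DataFrame:
    """Per-pathway PAL difference between two sample groups.

    ``labels`` aligns with the columns of ``pal_matrix``.  Reports the mean
    PAL per group, the difference (b - a), a two-sample t-test p-value, and
    its BH adjustment across pathways; sorted by |difference| descending.
    """
    labels = pd.Series(list(labels), index=pal_matrix.columns)
    cols_a = labels.index[labels == group_a]
    cols_b = labels.index[labels == group_b]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ParameterError("both groups must have at least one sample")
    a = pal_matrix[cols_a].to_numpy()
    b = pal_matrix[cols_b].to_numpy()
    diff = b.mean(axis=1) - a.mean(axis=1)
    if len(cols_a) >= 2 and len(cols_b) >= 2:
        with np.errstate(invalid="ignore"):
            pvals = stats.ttest_ind(b, a, axis=1).pvalue
        pvals = np.where(np.isfinite(pvals), pvals,
                         np.where(np.isclose(diff, 0.0), 1.0, 0.0))
    else:
        pvals = np.full(len(diff), np.nan)
    out = pd.DataFrame({
        f"mean_pal_{group_a}": a.mean(axis=1),
        f"mean_pal_{group_b}": b.mean(axis=1),
        "pal_diff": diff,
        "pvalue": pvals,
        "padj": bh_adjust(pvals) if np.isfinite(pvals).all() else pvals,
    }, index=pal_matrix.index)
    return out.reindex(out["pal_diff"].abs().sort_values(ascending=False).index)
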