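"""Four-model causal mediation classification of QTL triplets.

Each triplet (E, A, B) — a variant dosage E, a mediator trait A (elncRNA
intron PSI) and an outcome trait B (target expression or enhancer
chromatin mark) — is assigned one of four mediation topologies:

* independent — E is associated with A and B separately, with no A-B edge
  beyond what E induces;
* causal — A mediates the E->B association (the E->B partial association
  given A vanishes);
* reactive — the mirror image, with B mediating E->A;
* undecided — no model reaches confidence, or the interaction is more
  complex.

The test statistics are Fisher-z transformed Pearson and first-order
partial correlations, z = atanh(r) * sqrt(n - k - 3) with k conditioned
variables. Composite scores per model:

    causal      = min(|z(E,B)|, |z(A,B|E)|) - |z(E,B|A)|
    reactive    = min(|z(E,A)|, |z(A,B|E)|) - |z(E,A|B)|
    independent = min(|z(E,A)|, |z(E,B)|)   - |z(A,B|E)|

(The independent score conditions on the E->A association that triplet
construction already guarantees, which makes it exactly symmetric under
A<->B exchange.) Each score is calibrated against an empirical null built
by permuting the outcome across samples (B for the causal direction, A for
the reactive mirror, both pooled for the independent score) and converted
to a local false discovery rate with Gaussian-kernel density estimates and
an isotonic monotonicity adjustment. A triplet is labelled with the
lowest-lfdr model among those below the threshold (default 0.1); ties or
no qualifying model give "undecided".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

log = logging.getLogger(__name__)

__all__ = [
    "triplet_stats",
    "triplet_scores",
    "local_fdr",
    "classify_triplets",
    "MediationModel",
    "MediationResults",
    "summarize_calls",
]

MODELS = ("independent", "causal", "reactive")


def _as_matrix(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2:
        raise ValueError(f"{name} must be 1-D or 2-D")
    return x


def _row_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum(axis=1))
    bad = (sx == 0) | (sy == 0)
    if bad.any():
        which = "E/A/B (zero variance)"
        raise ValueError(f"zero variance in triplet vector(s): rows "
                         f"{np.flatnonzero(bad).tolist()} of {which}")
    r = (xc * yc).sum(axis=1) / (sx * sy)
    return np.clip(r, -1.0, 1.0)


def _partial(r_xy, r_xz, r_yz):
    """First-order partial correlation r(x,y | z); collinear cases -> 0."""
    denom2 = (1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom2 > 1e-12, (r_xy - r_xz * r_yz) / np.sqrt(np.maximum(denom2, 1e-300)), 0.0)
    return np.clip(r, -1.0, 1.0)


def _fisher_z(r: np.ndarray, n: int, k: int) -> np.ndarray:
    df = n - k - 3
    if df <= 0:
        raise ValueError("sample size too small for Fisher z")
    r = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
    return np.arctanh(r) * np.sqrt(df)


def triplet_stats(E, A, B) -> pd.DataFrame:
    """Correlation and partial-correlation statistics per triplet.

    E, A, B are (n_triplets, n_samples) matrices (or single vectors).
    Returns r(E,A), r(E,B), r(A,B), the three first-order partials and
    their Fisher-z statistics; collinear partials are set to 0 and flagged
    in the ``degenerate`` column.
    """
    E, A, B = (_as_matrix(x, n) for x, n in ((E, "E"), (A, "A"), (B, "B")))
    if not (E.shape == A.shape == B.shape):
        raise ValueError("E, A, B must share the same shape")
    n = E.shape[1]
    if n < 20:
        raise ValueError("need >= 20 complete samples per triplet")
    r_EA = _row_corr(E, A)
    r_EB = _row_corr(E, B)
    r_AB = _row_corr(A, B)
    denom_EB_A = (1.0 - r_EA ** 2) * (1.0 - r_AB ** 2)
    denom_EA_B = (1.0 - r_EB ** 2) * (1.0 - r_AB ** 2)
    denom_AB_E = (1.0 - r_EA ** 2) * (1.0 - r_EB ** 2)
    degenerate = (denom_EB_A <= 1e-12) | (denom_EA_B <= 1e-12) | (denom_AB_E <= 1e-12)
    df = pd.DataFrame({
        "r_EA": r_EA, "r_EB": r_EB, "r_AB": r_AB,
        "r_EB_A": _partial(r_EB, r_EA, r_AB),
        "r_EA_B": _partial(r_EA, r_EB, r_AB),
        "r_AB_E": _partial(r_AB, r_EA, r_EB),
        "n": n, "degenerate": degenerate,
    })
    for col, k in (("r_EA", 0), ("r_EB", 0), ("r_EB_A", 1), ("r_EA_B", 1), ("r_AB_E", 1)):
        df["z_" + col[2:]] = _fisher_z(df[col].to_numpy(), n, k)
    return df


def triplet_scores(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Composite per-model scores from triplet statistics."""
    z_EA = np.abs(stats_df["z_EA"].to_numpy())
    z_EB = np.abs(stats_df["z_EB"].to_numpy())
    z_EB_A = np.abs(stats_df["z_EB_A"].to_numpy())
    z_EA_B = np.abs(stats_df["z_EA_B"].to_numpy())
    z_AB_E = np.abs(stats_df["z_AB_E"].to_numpy())
    return pd.DataFrame({
        "causal": np.minimum(z_EB, z_AB_E) - z_EB_A,
        "reactive": np.minimum(z_EA, z_AB_E) - z_EA_B,
        "independent": np.minimum(z_EA, z_EB) - z_AB_E,
    }, index=stats_df.index)


def local_fdr(scores: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Empirical-null local false discovery rate per score.

    lfdr(s) = pi0 * f0(s) / f(s) with f0, f Gaussian-kernel density
    estimates (Silverman bandwidth) of the null and observed score
    ensembles. pi0 doubles the fraction of observed scores at or below the
    null median (which estimates pi0 * 1/2), capped at 1. The result is
    clipped to [0, 1] and made monotone non-increasing in the score by
    isotonic regression. Degenerate ensembles (all scores equal) give
    lfdr = 1 everywhere.
    """
    s = np.asarray(scores, dtype=float)
    s0 = np.asarray(null_scores, dtype=float)
    if s.size < 50 or s0.size < 500:
        raise ValueError("need >= 50 observed and >= 500 null scores")
    if np.ptp(s) == 0 or np.ptp(s0) == 0:
        return np.ones_like(s)
    pi0 = min(1.0, 2.0 * float(np.mean(s <= np.median(s0))))
    f0 = stats.gaussian_kde(s0, bw_method="silverman")
    f = stats.gaussian_kde(s, bw_method="silverman")
    with np.errstate(under="ignore"):
        dens0 = f0(s)
        dens = np.maximum(f(s), 1e-300)
    lfdr = np.clip(pi0 * dens0 / dens, 0.0, 1.0)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    return iso.fit_transform(s, lfdr)


def _null_scores(E, A, B, n_perms: int, seed: int) -> dict[str, np.ndarray]:
    """Permutation null score ensembles.

    The causal null permutes B across samples (preserving the E-A edge),
    the reactive null permutes A (the A<->B mirror), and the independent
    null pools both halves; the same permutation indices are used for both
    directions so A<->B exchange maps the ensembles onto each other
    exactly.
    """
    rng = np.random.default_rng(seed)
    n = E.shape[1]
    causal, reactive, indep = [], [], []
    for _ in range(n_perms):
        perm = rng.permutation(n)
        sc_b = triplet_scores(triplet_stats(E, A, B[:, perm]))
        sc_a = triplet_scores(triplet_stats(E, A[:, perm], B))
        causal.append(sc_b["causal"].to_numpy())
        reactive.append(sc_a["reactive"].to_numpy())
        indep.append(sc_b["independent"].to_numpy())
        indep.append(sc_a["independent"].to_numpy())
    return {"causal": np.concatenate(causal),
            "reactive": np.concatenate(reactive),
            "independent": np.concatenate(indep)}


def classify_triplets(E, A, B, lfdr_threshold: float = 0.1,
                      n_null_perms: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Classify triplets into independent/causal/reactive/undecided.

    E, A, B are (n_triplets, n_samples) matrices; A and B should be
    rank-normalised trait values and E allele dosages. Local FDRs are
    estimated per model from permutation nulls; each triplet is labelled
    with the lowest-lfdr model below ``lfdr_threshold``, with exact ties
    and no-qualifier cases labelled "undecided".
    """
    E, A, B = (_as_matrix(x, n) for x, n in ((E, "E"), (A, "A"), (B, "B")))
    m = E.shape[0]
    if m < 50:
        raise ValueError("need >= 50 triplets for lfdr estimation; "
                         "pool triplets across loci")
    stats_df = triplet_stats(E, A, B)
    scores = triplet_scores(stats_df)
    if n_null_perms is None:
        n_null_perms = max(2, int(np.ceil(1000 / m)))
    nulls = _null_scores(E, A, B, n_null_perms, seed)
    lfdrs = pd.DataFrame({mdl: local_fdr(scores[mdl].to_numpy(), nulls[mdl])
                          for mdl in MODELS}, index=scores.index)
    labels = []
    lf = lfdrs.to_numpy()
    for i in range(m):
        below = lf[i] < lfdr_threshold
        if not below.any():
            labels.append("undecided")
            continue
        vals = np.where(below, lf[i], np.inf)
        best = vals.min()
        if (vals == best).sum() > 1:
            labels.append("undecided")
        else:
            labels.append(MODELS[int(vals.argmin())])
    out = pd.concat([scores.add_prefix("score_"), lfdrs.add_prefix("lfdr_")], axis=1)
    out["model"] = labels
    return out


@dataclass
class MediationResults:
    """Fitted mediation classification.

    ``calls`` has one row per triplet with composite scores, per-model
    local FDRs and the assigned model label; ``stats`` holds the underlying
    correlation statistics.
    """

    calls: pd.DataFrame
    stats: pd.DataFrame
    lfdr_threshold: float

    def model_counts(self) -> pd.Series:
        order = ["causal", "reactive", "independent", "undecided"]
        return self.calls["model"].value_counts().reindex(order, fill_value=0)

    def model_proportions(self) -> pd.Series:
        c = self.model_counts()
        return c / c.sum()

    def summary(self) -> str:
        counts = self.model_counts()
        props = self.model_proportions()
        lines = ["Mediation classification", "=" * 40,
                 f"triplets:       {len(self.calls)}",
                 f"lfdr threshold: {self.lfdr_threshold}"]
        for mdl in counts.index:
            lines.append(f"{mdl:<12} {counts[mdl]:>6}  ({100 * props[mdl]:.1f}%)")
        return "\n".join(lines)


class MediationModel:
    """Four-model mediation classifier over a set of QTL triplets.

    Parameters
    ----------
    E, A, B : arrays (n_triplets, n_samples)
        Variant dosages, mediator traits and outcome traits per triplet.
        A and B are used as given; rank-normalise them upstream.
    triplet_ids : sequence, optional
        Index for the output frames.
    lfdr_threshold : float
        Local-FDR decision threshold (default 0.1).
    n_null_perms : int, optional
        Outcome permutations per triplet for the empirical null; defaults
        to enough for >= 1000 pooled null scores.
    seed : int
        Seed for the permutation null.
    """

    def __init__(self, E, A, B, triplet_ids=None, lfdr_threshold: float = 0.1,
                 n_null_perms: int | None = None, seed: int = 0):
        self.E = _as_matrix(E, "E")
        self.A = _as_matrix(A, "A")
        self.B = _as_matrix(B, "B")
        self.triplet_ids = triplet_ids
        self.lfdr_threshold = lfdr_threshold
        self.n_null_perms = n_null_perms
        self.seed = seed

    def fit(self) -> MediationResults:
        calls = classify_triplets(self.E, self.A, self.B,
                                  lfdr_threshold=self.lfdr_threshold,
                                  n_null_perms=self.n_null_perms, seed=self.seed)
        stats_df = triplet_stats(self.E, self.A, self.B)
        if self.triplet_ids is not None:
            calls.index = pd.Index(self.triplet_ids)
            stats_df.index = pd.Index(self.triplet_ids)
        return MediationResults(calls=calls, stats=stats_df,
                                lfdr_threshold=self.lfdr_threshold)


def summarize_calls(calls: pd.DataFrame,
                    elncrna: pd.Series | None = None,
                    junction_position: pd.Series | None = None) -> dict:
    """Summaries of mediation calls.

    ``elncrna`` maps triplet index -> elncRNA id; an elncRNA is counted
    causal when at least one of its triplets is labelled causal.
    ``junction_position`` maps triplet index -> "5prime"/"3prime"; when
    given, a two-tailed Fisher test contrasts the 5'/3' split of causal vs
    non-causal triplets.
    """
    counts = calls["model"].value_counts().reindex(
        ["causal", "reactive", "independent", "undecided"], fill_value=0)
    out = {"model_counts": counts.to_dict(),
           "model_proportions": (counts / max(1, counts.sum())).to_dict()}
    if elncrna is not None:
        per = calls.assign(elncrna=elncrna).groupby("elncrna")["model"]
        causal_by_gene = per.apply(lambda s: (s == "causal").any())
        out["n_elncrnas"] = int(causal_by_gene.size)
        out["n_causal_elncrnas"] = int(causal_by_gene.sum())
        out["causal_elncrna_fraction"] = float(causal_by_gene.mean())
    if junction_position is not None:
        is_causal = (calls["model"] == "causal").to_numpy()
        is_5p = (junction_position.loc[calls.index] == "5prime").to_numpy()
        table = [[int((is_causal & is_5p).sum()), int((is_causal & ~is_5p).sum())],
                 [int((~is_causal & is_5p).sum()), int((~is_causal & ~is_5p).sum())]]
        orr, p = stats.fisher_exact(table, alternative="two-sided")
        out["junction_split_table"] = table
        out["junction_split_fisher_p"] = float(p)
        out["junction_split_odds_ratio"] = float(orr)
    return out
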