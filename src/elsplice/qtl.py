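"""Cis-QTL mapping with permutation-calibrated gene-level thresholds.

Variants with minor allele frequency strictly above 5% located in the same
topologically associating domain (TAD) as a trait are tested by ordinary
least squares of the rank-inverse-normal transformed trait on allele
dosage. Gene-level significance is calibrated by permuting the trait 1,000
times, recording the maximum absolute correlation over cis variants
(r_max) per permutation, and requiring the observed maximum to exceed 95%
of the permuted r_max values; nominal p-values within each TAD are then
Benjamini-Hochberg corrected (FDR < 5%).

The same machinery maps splicing (sQTL), expression (eQTL) and chromatin
(cQTL) traits; joint triplets pair a variant with an elncRNA splicing
mediator and an expression/chromatin outcome for downstream mediation
analysis, after excluding variants also associated with elncRNA expression
itself or with splicing of the putative target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicInterval, GenotypeMatrix, PhenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "rank_normalize",
    "maf_filter",
    "cis_associate",
    "gene_level_permutation",
    "bh_fdr",
    "assign_tads",
    "CisQtlModel",
    "CisQtlResults",
    "predict_targets",
    "build_joint_triplets",
    "zscore_to_slope",
    "replication_check",
]


def rank_normalize(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (ties averaged, mean-centred)."""
    x = np.asarray(x, dtype=float)
    if np.sum(np.isfinite(x)) < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanstd(x) == 0:
        raise ValueError("constant trait vector")
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    ranks = stats.rankdata(x[ok], method="average")
    z = stats.norm.ppf(ranks / (ok.sum() + 1))
    out[ok] = z - z.mean()
    return out


def maf_filter(gm: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep variants with MAF strictly greater than ``threshold``."""
    keep = gm.maf() > threshold
    if not keep.any():
        log.warning("no variants pass the MAF filter")
    return gm.subset_variants(gm.variants.index[keep.to_numpy()])


def _center(a: np.ndarray, axis=0) -> np.ndarray:
    return a - a.mean(axis=axis, keepdims=True)


def cis_associate(trait: np.ndarray, genotypes: np.ndarray,
                  min_samples: int = 20) -> pd.DataFrame:
    """Per-variant OLS of a (rank-normalised) trait on dosage.

    ``genotypes`` is (n_samples, n_variants); returns a DataFrame with
    slope, r and two-tailed p (from the t statistic, df = n - 2) per
    variant. Zero-variance variants are skipped (NaN row).
    """
    y = np.asarray(trait, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(G), axis=1)
    y, G = y[ok], G[ok]
    n = y.size
    if n < min_samples:
        raise ValueError(f"only {n} complete samples; need >= {min_samples}")
    yc = y - y.mean()
    Gc = _center(G)
    ss_g = (Gc ** 2).sum(axis=0)
    ss_y = float((yc ** 2).sum())
    cov = yc @ Gc
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(ss_g > 0, cov / ss_g, np.nan)
        r = np.where(ss_g > 0, cov / np.sqrt(ss_g * ss_y), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    skipped = ~(ss_g > 0)
    if skipped.any():
        log.warning("skipped %d zero-variance variants", skipped.sum())
    return pd.DataFrame({"slope": slope, "r": r, "p": np.where(np.isfinite(r), p, np.nan),
                         "n": n})


def gene_level_permutation(trait: np.ndarray, genotypes: np.ndarray,
                           n_perm: int = 1000, seed: int = 0) -> tuple[bool, np.ndarray]:
    """Permutation calibration of the per-gene maximum cis association.

    The trait is shuffled across samples ``n_perm`` times; each permutation
    records r_max, the maximum |r| over cis variants. The gene passes iff
    its observed r_max exceeds 95% of the permuted values. Returns
    (passed, r_max distribution).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(trait, dtype=float)
    G = np.asarray(genotypes, dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(G), axis=1)
    y, G = y[ok], G[ok]
    n = y.size
    yc = y - y.mean()
    Gc = _center(G)
    ss_g = (Gc ** 2).sum(axis=0)
    keep = ss_g > 0
    Gc = Gc[:, keep]
    gnorm = np.sqrt(ss_g[keep])
    ynorm = float(np.sqrt((yc ** 2).sum()))
    r_obs = float(np.max(np.abs((yc @ Gc) / (gnorm * ynorm))))
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = yc[idx]                                     # permuted, still centred
    R = np.abs(Yp @ Gc) / (gnorm[None, :] * ynorm)
    r_max = R.max(axis=1)
    passed = bool(np.mean(r_max < r_obs) > 0.95)
    return passed, r_max


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_tads(positions: pd.DataFrame, tads: list[GenomicInterval]) -> pd.Series:
    """Map each (chrom, pos) row to the name of its containing TAD (or NaN)."""
    out = []
    for _, row in positions.iterrows():
        hit = None
        for i, tad in enumerate(tads):
            if tad.chrom == str(row["chrom"]) and tad.start <= int(row["pos"]) < tad.end:
                hit = tad.name or f"tad_{i}"
                break
        out.append(hit)
    return pd.Series(out, index=positions.index, name="tad")


@dataclass
class CisQtlResults:
    """Per-(variant, trait) association records from a fitted CisQtlModel.

    ``records`` columns: variant_id, trait_id, kind, tad, slope, r, p,
    perm_pass (gene-level permutation verdict, shared by all variants of a
    trait), q (BH within the trait's TAD variant set).
    """

    records: pd.DataFrame
    kind: str
    n_perm: int

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        r = self.records
        return r[(r["perm_pass"]) & (r["q"] < fdr)]

    def best_per_trait(self) -> pd.DataFrame:
        """The most significant variant per trait among significant records."""
        sig = self.significant()
        if sig.empty:
            return sig
        return sig.loc[sig.groupby("trait_id")["p"].idxmin()]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            f"Cis-QTL mapping results ({self.kind})",
            "=" * 40,
            f"traits tested:        {self.records['trait_id'].nunique()}",
            f"variant-trait tests:  {len(self.records)}",
            f"permutations/trait:   {self.n_perm}",
            f"significant records:  {len(sig)}",
            f"traits with >=1 QTL:  {sig['trait_id'].nunique() if len(sig) else 0}",
        ]
        return "\n".join(lines)


class CisQtlModel:
    """Cis-QTL scan of one phenotype matrix against a genotype matrix.

    Parameters
    ----------
    phenotypes : PhenotypeMatrix
        Trait x sample values (expression RPKM, splicing PSI or chromatin
        CPM; PSI traits are typically intron keys ``chrom:start:end:clu``).
    genotypes : GenotypeMatrix
    tads : list of GenomicInterval
        The cis-windows; traits and variants are paired within a shared TAD.
    trait_positions : DataFrame, optional
        chrom/pos per trait id. When omitted, positions are parsed from
        LeafCutter-style trait ids.
    maf_threshold : float
        Variants with MAF <= threshold are excluded (default 0.05, strict).
    n_perm, seed : int
        Gene-level permutation scheme parameters.
    """

    def __init__(self, phenotypes: PhenotypeMatrix, genotypes: GenotypeMatrix,
                 tads: list[GenomicInterval], trait_positions: pd.DataFrame | None = None,
                 maf_threshold: float = 0.05, n_perm: int = 1000, seed: int = 0,
                 min_samples: int = 20):
        self.phenotypes = phenotypes
        self.genotypes = maf_filter(genotypes, maf_threshold)
        self.tads = tads
        self.n_perm = n_perm
        self.seed = seed
        self.min_samples = min_samples
        if trait_positions is None:
            trait_positions = self._positions_from_ids(phenotypes.traits)
        self.trait_positions = trait_positions

    @staticmethod
    def _positions_from_ids(traits: list[str]) -> pd.DataFrame:
        rows = []
        for t in traits:
            parts = str(t).split(":")
            if len(parts) >= 3:
                rows.append((t, parts[0], (int(parts[1]) + int(parts[2])) // 2))
            else:
                raise ValueError(f"cannot parse a position from trait id {t!r}; "
                                 "provide trait_positions")
        return pd.DataFrame(rows, columns=["trait", "chrom", "pos"]).set_index("trait")

    def fit(self) -> CisQtlResults:
        gm = self.genotypes
        common = [s for s in self.phenotypes.samples if s in gm.samples]
        if len(common) < self.min_samples:
            raise ValueError("too few shared samples between phenotypes and genotypes")
        sidx = [gm.samples.index(s) for s in common]
        dosages = gm.dosages[sidx]
        trait_tads = assign_tads(self.trait_positions, self.tads)
        var_pos = gm.variants[["chrom", "pos"]].copy()
        var_tads = assign_tads(var_pos, self.tads)
        records = []
        rng = np.random.default_rng(self.seed)
        for trait in self.phenotypes.traits:
            tad = trait_tads.get(trait)
            if tad is None or (isinstance(tad, float) and np.isnan(tad)):
                log.warning("trait %s has no containing TAD; skipped", trait)
                continue
            vmask = (var_tads == tad).to_numpy()
            if not vmask.any():
                continue
            y = self.phenotypes.values.loc[trait, common].to_numpy(dtype=float)
            ok = np.isfinite(y)
            if ok.sum() < self.min_samples:
                log.warning("trait %s: too few non-missing samples; skipped", trait)
                continue
            try:
                yr = rank_normalize(y)
            except ValueError:
                log.warning("trait %s: constant values; skipped", trait)
                continue
            G = dosages[:, vmask]
            assoc = cis_associate(yr, G, min_samples=self.min_samples)
            trait_seed = int(rng.integers(0, 2 ** 31 - 1))
            passed, _ = gene_level_permutation(yr, G, n_perm=self.n_perm,
                                               seed=trait_seed)
            finite = assoc["p"].notna()
            q = np.full(len(assoc), np.nan)
            if finite.any():
                q[finite.to_numpy()] = bh_fdr(assoc.loc[finite, "p"].to_numpy())
            vids = gm.variants.index[vmask]
            for k, vid in enumerate(vids):
                records.append({"variant_id": vid, "trait_id": trait,
                                "kind": self.phenotypes.kind, "tad": tad,
                                "slope": assoc["slope"].iloc[k], "r": assoc["r"].iloc[k],
                                "p": assoc["p"].iloc[k], "perm_pass": passed,
                                "q": q[k], "n": assoc["n"].iloc[k]})
        cols = ["variant_id", "trait_id", "kind", "tad", "slope", "r", "p",
                "perm_pass", "q", "n"]
        df = pd.DataFrame(records, columns=cols)
        return CisQtlResults(records=df, kind=self.phenotypes.kind, n_perm=self.n_perm)


def predict_targets(elnc_eqtls: pd.DataFrame, pcg_eqtls: pd.DataFrame) -> pd.DataFrame:
    """Pair elncRNAs with putative targets via shared significant eQTLs.

    Both inputs are significant-record frames with columns variant_id,
    trait_id and tad. A pair (elncRNA, gene) is reported iff both lie in
    the same TAD and some variant is a significant eQTL for both.
    """
    merged = elnc_eqtls.merge(pcg_eqtls, on=["variant_id", "tad"],
                              suffixes=("_elnc", "_target"))
    pairs = merged[["trait_id_elnc", "trait_id_target", "tad"]].drop_duplicates()
    return pairs.rename(columns={"trait_id_elnc": "elncrna",
                                 "trait_id_target": "target"}).reset_index(drop=True)


def build_joint_triplets(
    elnc_sqtls: pd.DataFrame,
    outcome_qtls: pd.DataFrame,
    elnc_eqtls: pd.DataFrame | None = None,
    target_sqtls: pd.DataFrame | None = None,
    mediator_gene: pd.Series | None = None,
    mode: str = "expression",
) -> pd.DataFrame:
    """Assemble joint (variant, mediator, outcome) triplets with audit flags.

    ``elnc_sqtls``: significant sQTL records of elncRNA introns (columns
    variant_id, trait_id, tad). ``outcome_qtls``: significant eQTL (mode
    "expression") or chromatin cQTL (mode "chromatin") records of outcome
    traits. ``elnc_eqtls``: significant eQTLs of elncRNA *expression* —
    variants present there for the mediator's gene are flagged and
    excluded. ``target_sqtls``: significant sQTLs of the outcome genes —
    likewise excluded. ``mediator_gene`` maps mediator trait id (intron) to
    its elncRNA gene id.

    Returns one row per candidate triplet with boolean columns
    ``excluded_elnc_eqtl``, ``excluded_target_sqtl`` and ``included``.
    """
    if mode not in ("expression", "chromatin"):
        raise ValueError("mode must be 'expression' or 'chromatin'")
    joint = elnc_sqtls.merge(outcome_qtls, on=["variant_id", "tad"],
                             suffixes=("_med", "_out"))
    if joint.empty:
        return pd.DataFrame(columns=["variant_id", "mediator", "elncrna", "outcome",
                                     "tad", "excluded_elnc_eqtl",
                                     "excluded_target_sqtl", "included"])
    rows = []
    elnc_pairs = (set(zip(elnc_eqtls["variant_id"], elnc_eqtls["trait_id"]))
                  if elnc_eqtls is not None and len(elnc_eqtls) else set())
    tgt_pairs = (set(zip(target_sqtls["variant_id"], target_sqtls.get(
        "gene_id", target_sqtls["trait_id"])))
        if target_sqtls is not None and len(target_sqtls) else set())
    for _, row in joint.iterrows():
        mediator = row["trait_id_med"]
        gene = (mediator_gene.get(mediator) if mediator_gene is not None else mediator)
        ex_e = (row["variant_id"], gene) in elnc_pairs
        ex_t = mode == "expression" and (row["variant_id"], row["trait_id_out"]) in tgt_pairs
        rows.append({"variant_id": row["variant_id"], "mediator": mediator,
                     "elncrna": gene, "outcome": row["trait_id_out"],
                     "tad": row["tad"], "excluded_elnc_eqtl": ex_e,
                     "excluded_target_sqtl": ex_t,
                     "included": not (ex_e or ex_t)})
    return pd.DataFrame(rows).drop_duplicates(
        subset=["variant_id", "mediator", "outcome"]).reset_index(drop=True)


def zscore_to_slope(z: float, allele_freq: float, n: int) -> float:
    """Convert a replication Z-score to a regression slope.

    slope = z / sqrt(2 f (1 - f) (n + z^2)).
    """
    if not 0.0 < allele_freq < 1.0:
        raise ValueError("allele frequency must lie in (0, 1)")
    if n <= 0:
        raise ValueError("sample size must be positive")
    return float(z / np.sqrt(2.0 * allele_freq * (1.0 - allele_freq) * (n + z ** 2)))


def replication_check(discovery: pd.DataFrame, replication: pd.DataFrame) -> pd.DataFrame:
    """Flag discovery associations replicated in an independent dataset.

    Inputs are keyed by (variant_id, trait_id); ``discovery`` needs a
    ``slope`` column and ``replication`` needs ``p`` and an effect column
    (``slope`` or ``z``). An association replicates iff its BH-adjusted
    replication p < 0.05 and the effect signs agree.
    """
    eff_col = "slope" if "slope" in replication.columns else "z"
    rep = replication.copy()
    rep["q_rep"] = bh_fdr(rep["p"].to_numpy())
    merged = discovery.merge(rep, on=["variant_id", "trait_id"],
                             suffixes=("_disc", "_rep"), how="left")
    eff_rep = merged[f"{eff_col}_rep"] if f"{eff_col}_rep" in merged else merged[eff_col]
    slope_disc = merged["slope_disc"] if "slope_disc" in merged else merged["slope"]
    merged["replicated"] = ((merged["q_rep"] < 0.05)
                            & (np.sign(eff_rep) == np.sign(slope_disc))
                            & merged["q_rep"].notna())
    return merged
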