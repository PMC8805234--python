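"""Polygenic instruments: weight harmonisation, clumping+thresholding,
weighted scoring, and within-stratum standardisation.

A weight table carries per-SNP effect-allele weights (typically exported
from an external summary-statistic method); scoring is a weighted sum of
effect-allele dosages after harmonising the table's allele orientation
to the cohort's dosage coding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreVector",
    "read_weight_table",
    "write_weight_table",
    "harmonize",
    "clump_and_threshold",
    "score",
    "standardize_within_strata",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

WEIGHT_COLUMNS = ["id", "chrom", "pos", "ea", "oa", "weight"]


def read_weight_table(path) -> pd.DataFrame:
    """Read a TSV weight table (id, chrom, pos, ea, oa, weight[, p, eaf])."""
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in WEIGHT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if tab["id"].duplicated().any():
        raise ValueError("weight table has duplicate SNP ids")
    if not np.isfinite(tab["weight"]).all():
        raise ValueError("weight table has non-finite weights")
    return tab


def write_weight_table(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(weights: pd.DataFrame, snp_meta: pd.DataFrame) -> pd.DataFrame:
    """Align a weight table to the cohort's dosage orientation.

    The cohort codes dosages on ``snp_meta.ea``.  Matching alleles are
    kept; swapped effect/other alleles get ``flip=True`` (dosage is
    re-oriented at scoring time, the weight's sign is untouched); strand
    complements are resolved; palindromic (A/T, C/G) SNPs are dropped
    when the cohort frequency is in (0.4, 0.6) and otherwise resolved by
    comparing the weight table's effect-allele frequency (``eaf``) with
    the cohort frequency when available.  Unmatched SNPs are dropped
    with a reason; zero survivors is a hard error.

    Returns the aligned table with ``flip`` plus a ``dropped`` attribute
    (DataFrame of id, reason) in ``.attrs``.
    """
    meta = snp_meta.set_index("id")
    rows = []
    dropped = []
    for rec in weights.itertuples(index=False):
        if rec.id not in meta.index:
            dropped.append((rec.id, "not_in_cohort"))
            continue
        site = meta.loc[rec.id]
        ca, co, freq = site["ea"], site["oa"], site.get("freq", np.nan)
        wa, wo = rec.ea, rec.oa
        if _is_palindromic(wa, wo):
            if np.isfinite(freq) and 0.4 < freq < 0.6:
                dropped.append((rec.id, "palindromic_ambiguous"))
                continue
            eaf = getattr(rec, "eaf", None)
            if eaf is not None and np.isfinite(eaf) and np.isfinite(freq):
                flip = (eaf < 0.5) != (freq < 0.5)
            elif {wa, wo} == {ca, co}:
                flip = wa != ca  # assume same strand
            else:
                dropped.append((rec.id, "allele_mismatch"))
                continue
        elif wa == ca and wo == co:
            flip = False
        elif wa == co and wo == ca:
            flip = True
        elif _COMPLEMENT.get(wa) == ca and _COMPLEMENT.get(wo) == co:
            flip = False
        elif _COMPLEMENT.get(wa) == co and _COMPLEMENT.get(wo) == ca:
            flip = True
        else:
            dropped.append((rec.id, "allele_mismatch"))
            continue
        row = rec._asdict()
        row["flip"] = flip
        rows.append(row)
    if not rows:
        raise ValueError("no SNPs survived harmonisation")
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = pd.DataFrame(dropped, columns=["id", "reason"])
    return out


def clump_and_threshold(stats: pd.DataFrame, reference: pd.DataFrame,
                        p_max: float = 5e-8, r2_max: float = 0.1,
                        window_kb: float = 250.0) -> list[str]:
    """Greedy LD clumping with a p-value threshold.

    SNPs are visited in ascending (p, id) order; a SNP is accepted iff
    its p-value is at most ``p_max`` and its squared genotype
    correlation with every previously accepted SNP on the same
    chromosome within ``window_kb`` is at most ``r2_max``.  ``reference``
    is an individuals x SNPs genotype DataFrame (columns = SNP ids).
    Returns the accepted SNP ids in acceptance order.
    """
    if "p" not in stats.columns:
        raise ValueError("clump_and_threshold requires a 'p' column")
    cand = stats.sort_values(["p", "id"], kind="stable")
    std = {}
    for snp_id in cand["id"]:
        if snp_id in reference.columns:
            g = reference[snp_id].to_numpy(dtype=float)
            sd = g.std()
            std[snp_id] = (g - g.mean()) / sd if sd > 0 else None
    accepted: list[str] = []
    acc_rows: list[tuple[int, int, str]] = []  # (chrom, pos, id)
    window = window_kb * 1000.0
    n_ref = len(reference)
    for rec in cand.itertuples(index=False):
        if rec.p > p_max:
            continue
        if rec.id not in std:
            warnings.warn(f"SNP {rec.id} missing from reference genotypes; dropped")
            continue
        g = std[rec.id]
        if g is None:
            continue  # monomorphic in reference
        ok = True
        for chrom, pos, other in acc_rows:
            if chrom == rec.chrom and abs(pos - rec.pos) <= window:
                r = float(g @ std[other]) / n_ref
                if r * r > r2_max:
                    ok = False
                    break
        if ok:
            accepted.append(rec.id)
            acc_rows.append((rec.chrom, rec.pos, rec.id))
    return accepted


@dataclass
class ScoreVector:
    """Per-individual weighted allele score."""

    score: pd.Series
    n_snps_used: int
    snps_dropped: list[tuple[str, str]] = field(default_factory=list)
    n_imputed: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = self.score.rename("score").to_frame()
        out["n_snps_used"] = self.n_snps_used
        return out


def score(dosages: pd.DataFrame, weights: pd.DataFrame) -> ScoreVector:
    """Weighted sum of effect-allele dosages.

    ``dosages`` columns are SNP ids (fractional expected dosages from
    ambiguous duo sites are allowed); ``weights`` is a harmonised table
    with a ``flip`` column.  Sporadically missing dosages are
    mean-imputed per SNP; all-missing SNPs are dropped with a warning.
    """
    ids = [s for s in weights["id"] if s in dosages.columns]
    absent = [(s, "no_dosage_column") for s in weights["id"] if s not in dosages.columns]
    wtab = weights.set_index("id").loc[ids]
    d = dosages[ids].to_numpy(dtype=float).copy()
    flip = wtab["flip"].to_numpy(dtype=bool) if "flip" in wtab else np.zeros(len(ids), bool)
    d[:, flip] = 2.0 - d[:, flip]

    dropped = list(absent)
    keep = np.ones(len(ids), dtype=bool)
    n_imputed = 0
    for j, snp_id in enumerate(ids):
        col = d[:, j]
        miss = np.isnan(col)
        if miss.all():
            keep[j] = False
            dropped.append((snp_id, "all_missing"))
            warnings.warn(f"SNP {snp_id} has no observed dosages; dropped from score")
        elif miss.any():
            col[miss] = col[~miss].mean()
            n_imputed += int(miss.sum())
    d = d[:, keep]
    w = wtab["weight"].to_numpy(dtype=float)[keep]
    values = pd.Series(d @ w, index=dosages.index, name="score")
    return ScoreVector(values, int(keep.sum()), dropped, n_imputed)


def _merge_sparse_strata(strata: pd.Series, min_size: int) -> pd.Series:
    """Merge strata smaller than ``min_size`` into the nearest label."""
    labels = strata.copy()
    while True:
        sizes = labels.value_counts()
        if len(sizes) <= 1:
            break
        small = sizes[sizes < min_size]
        if small.empty:
            break
        ordered = sorted(sizes.index)
        lbl = sorted(small.index)[0]
        i = ordered.index(lbl)
        neighbours = [ordered[j] for j in (i - 1, i + 1) if 0 <= j < len(ordered)]
        try:
            target = min(neighbours, key=lambda nb: abs(float(nb) - float(lbl)))
        except (TypeError, ValueError):
            target = neighbours[0]
        labels = labels.replace({lbl: target})
    return labels


def standardize_within_strata(values: pd.Series, strata: pd.Series,
                              min_size: int = 10) -> pd.Series:
    """Z-score ``values`` within strata (e.g. 1-year maternal age bands).

    Strata smaller than ``min_size`` are merged with the nearest label
    before standardising.  A zero-variance stratum raises, naming it.
    Missing values are passed through as NaN and do not contribute to
    stratum moments.
    """
    values = pd.Series(values)
    strata = pd.Series(strata).loc[values.index]
    merged = _merge_sparse_strata(strata[values.notna()], min_size)
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for lbl, idx in merged.groupby(merged).groups.items():
        v = values.loc[idx]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero-variance stratum: {lbl!r}")
        out.loc[idx] = (v - v.mean()) / sd
    return out
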