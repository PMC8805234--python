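"""Recover maternal transmitted / non-transmitted dosages from duos.

Given hard-call genotypes for mother and child (optionally father), the
maternal allele transmitted to the child is determined exactly at most
sites: whenever the mother or child is homozygous, or the child is
heterozygous with a homozygous mother, the transmitted allele is forced.
The only ambiguous configuration is a heterozygous mother with a
heterozygous child; a homozygous father then resolves it, otherwise a
policy applies — the default uses the expected dosage 0.5 (unbiased for
score building under the symmetric prior), the alternative drops the
site.  Impossible configurations are flagged as Mendelian errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_NAMES",
    "DuoResolution",
    "CohortResolution",
    "resolve_duo",
    "resolve_cohort",
    "ambiguity_rate_hwe",
]

# status codes
FORCED = 0
FATHER_RESOLVED = 1
AMBIGUOUS_EXPECTED = 2
AMBIGUOUS_DROPPED = 3
MENDEL_ERROR = 4

STATUS_NAMES = {
    FORCED: "forced",
    FATHER_RESOLVED: "father_resolved",
    AMBIGUOUS_EXPECTED: "ambiguous_expected",
    AMBIGUOUS_DROPPED: "ambiguous_dropped",
    MENDEL_ERROR: "mendel_error",
}

_HAPS = {0: (0,), 1: (0, 1), 2: (1,)}


def _valid_transmissions(m: int, c: int, f: int | None) -> tuple[int, ...]:
    """Maternal alleles t_m compatible with child = t_m + t_p."""
    paternal = _HAPS[f] if f is not None else (0, 1)
    return tuple(sorted({tm for tm in _HAPS[m] for tp in paternal if tm + tp == c}))


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lookup tables indexed by (mother, child, father-or-3).

    Returns (transmitted_expected, status_expected, transmitted_drop,
    status_drop); father code 3 means 'missing'.
    """
    t_exp = np.full((3, 3, 4), np.nan)
    s_exp = np.full((3, 3, 4), MENDEL_ERROR, dtype=np.int8)
    t_drop = np.full((3, 3, 4), np.nan)
    s_drop = np.full((3, 3, 4), MENDEL_ERROR, dtype=np.int8)
    for m in range(3):
        for c in range(3):
            for fi in range(4):
                f = None if fi == 3 else fi
                valid = _valid_transmissions(m, c, f)
                duo_valid = _valid_transmissions(m, c, None)
                if not valid:
                    continue  # Mendelian error (maternal or paternal)
                if len(valid) == 1:
                    t = float(valid[0])
                    status = FORCED if len(duo_valid) == 1 else FATHER_RESOLVED
                    t_exp[m, c, fi] = t_drop[m, c, fi] = t
                    s_exp[m, c, fi] = s_drop[m, c, fi] = status
                else:  # symmetric ambiguity: mother het, child het, father het/missing
                    t_exp[m, c, fi] = 0.5
                    s_exp[m, c, fi] = AMBIGUOUS_EXPECTED
                    s_drop[m, c, fi] = AMBIGUOUS_DROPPED
    return t_exp, s_exp, t_drop, s_drop


_T_EXP, _S_EXP, _T_DROP, _S_DROP = _build_tables()


@dataclass
class DuoResolution:
    """Resolution of one mother–child site."""

    transmitted: float  # NaN for mendel_error / ambiguous_dropped
    nontransmitted: float
    status: str


def resolve_duo(mother_g: int, child_g: int, father_g: int | None = None,
                policy: str = "expected") -> DuoResolution:
    """Resolve one site. ``policy`` is 'expected' (default) or 'drop'."""
    for name, g in (("mother", mother_g), ("child", child_g)):
        if g not in (0, 1, 2):
            raise ValueError(f"{name} dosage must be in {{0,1,2}}, got {g}")
    if father_g is not None and father_g not in (0, 1, 2):
        raise ValueError(f"father dosage must be in {{0,1,2}}, got {father_g}")
    fi = 3 if father_g is None else father_g
    if policy == "expected":
        t, s = _T_EXP[mother_g, child_g, fi], _S_EXP[mother_g, child_g, fi]
    elif policy == "drop":
        t, s = _T_DROP[mother_g, child_g, fi], _S_DROP[mother_g, child_g, fi]
    else:
        raise ValueError(f"unknown policy {policy!r}")
    nt = mother_g - t if np.isfinite(t) else np.nan
    return DuoResolution(float(t), float(nt), STATUS_NAMES[int(s)])


@dataclass
class CohortResolution:
    """Element-wise duo resolution over a cohort.

    ``transmitted``/``nontransmitted`` are (n, m) float arrays with NaN
    at Mendelian-error or dropped-ambiguous sites; ``status`` holds the
    per-site integer codes.  ``snp_qc`` summarises per-SNP ambiguity and
    Mendelian-error rates; ``excluded_snps`` lists columns whose
    Mendelian-error rate exceeded the exclusion threshold (their dosages
    are set entirely to NaN).
    """

    transmitted: np.ndarray
    nontransmitted: np.ndarray
    status: np.ndarray
    snp_qc: pd.DataFrame
    excluded_snps: list[int]

    def status_counts(self) -> dict[str, int]:
        return {name: int((self.status == code).sum()) for code, name in STATUS_NAMES.items()}


def resolve_cohort(mother: np.ndarray, child: np.ndarray,
                   father: np.ndarray | None = None, policy: str = "expected",
                   mendel_exclude_threshold: float = 0.01) -> CohortResolution:
    """Resolve every site of aligned (n, m) genotype matrices."""
    mother = np.asarray(mother)
    child = np.asarray(child)
    if mother.shape != child.shape:
        raise ValueError(f"shape mismatch: mother {mother.shape} vs child {child.shape}")
    if father is not None and np.asarray(father).shape != mother.shape:
        raise ValueError("father matrix shape mismatch")
    for name, g in (("mother", mother), ("child", child)) + (
        (("father", father),) if father is not None else ()
    ):
        bad = ~np.isin(g, (0, 1, 2))
        if bad.any():
            raise ValueError(f"{name} dosages outside {{0,1,2}} at {int(bad.sum())} sites")

    fi = np.full(mother.shape, 3, dtype=np.int8) if father is None else np.asarray(father)
    t_tab, s_tab = (_T_EXP, _S_EXP) if policy == "expected" else (_T_DROP, _S_DROP)
    if policy not in ("expected", "drop"):
        raise ValueError(f"unknown policy {policy!r}")
    transmitted = t_tab[mother, child, fi]
    status = s_tab[mother, child, fi]
    nontransmitted = mother - transmitted

    n = mother.shape[0]
    mendel_rate = (status == MENDEL_ERROR).mean(axis=0)
    ambig = np.isin(status, (AMBIGUOUS_EXPECTED, AMBIGUOUS_DROPPED)).mean(axis=0)
    excluded = np.flatnonzero(mendel_rate > mendel_exclude_threshold).tolist()
    transmitted = transmitted.copy()
    nontransmitted = nontransmitted.copy()
    if excluded:
        transmitted[:, excluded] = np.nan
        nontransmitted[:, excluded] = np.nan
    snp_qc = pd.DataFrame(
        {
            "ambiguous_rate": ambig,
            "mendel_error_rate": mendel_rate,
            "excluded": np.isin(np.arange(mother.shape[1]), excluded),
        }
    )
    return CohortResolution(transmitted, nontransmitted, status, snp_qc, excluded)


def ambiguity_rate_hwe(p: float) -> float:
    """Expected ambiguous-site rate for a duo (no father) under HWE.

    Enumerates the mother x father x child-transmission table at allele
    frequency ``p`` with random mating: a site is ambiguous iff mother
    and child are both heterozygous, which requires the maternal
    transmitted allele and the paternal transmitted allele to differ.
    """
    hwe = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
    total = 0.0
    for m, pm in hwe.items():
        for f, pf in hwe.items():
            for tm in _HAPS[m]:
                for tp in _HAPS[f]:
                    p_t = pm * pf / (len(_HAPS[m]) * len(_HAPS[f]))
                    child = tm + tp
                    if m == 1 and child == 1:
                        total += p_t
    return total
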