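"""Codominant SSR statistics: diversity, F-statistics, distances, AMOVA.

Implements the classical toolbox for small microsatellite surveys of
fragmented populations:

* per-subpopulation diversity (Na, effective alleles, Ho, He, unbiased He,
  Shannon's I, fixation index F) and Botstein's polymorphism information
  content (PIC);
* chi-square Hardy–Weinberg tests;
* Wright's F-statistics in the Nei (1977) heterozygosity decomposition with
  permutation significance, plus a Weir–Cockerham theta estimator;
* Nei (1978) unbiased genetic distance and Wright's island-model gene flow;
* EM estimation of null-allele frequencies and the "excluding null alleles"
  (ENA) correction of FST with locus bootstrap intervals;
* two-level AMOVA on an allele-mismatch distance with permutation tests;
* principal coordinates analysis; and the Evanno ΔK statistic for choosing
  the number of genetic clusters from replicate clustering log-probabilities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleFrequencies",
    "DiversitySummary",
    "FStatistics",
    "AmovaResult",
    "NullAlleleEstimates",
    "allele_frequencies",
    "diversity",
    "pic",
    "hwe_chisq",
    "f_statistics",
    "nei_unbiased_distance",
    "gene_flow",
    "null_allele_em",
    "weir_cockerham_fst",
    "fst_ena",
    "amova",
    "pcoa",
    "evanno_delta_k",
]


# -- allele frequencies -------------------------------------------------------


@dataclass
class AlleleFrequencies:
    """Allele frequencies per (subpopulation, locus) over non-missing calls."""

    freqs: dict[tuple[str, str], dict[int, float]]
    n_typed: dict[tuple[str, str], int]
    subpopulations: list[str]
    loci: list[str]

    def alleles(self, locus: str) -> list[int]:
        """All alleles observed at a locus across subpopulations, sorted."""
        out: set[int] = set()
        for pop in self.subpopulations:
            out.update(self.freqs.get((pop, locus), {}))
        return sorted(out)

    def pooled(self, locus: str) -> dict[int, float]:
        """Sample-size-weighted pooled frequencies at a locus."""
        counts: dict[int, float] = {}
        total = 0.0
        for pop in self.subpopulations:
            n = self.n_typed.get((pop, locus), 0)
            for a, f in self.freqs.get((pop, locus), {}).items():
                counts[a] = counts.get(a, 0.0) + f * 2 * n
            total += 2 * n
        if total == 0:
            return {}
        return {a: c / total for a, c in counts.items()}


def allele_frequencies(g: GenotypeTable) -> AlleleFrequencies:
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_typed: dict[tuple[str, str], int] = {}
    missing = g.is_missing()
    for pop in g.subpopulations:
        idx = g.pop_indices(pop)
        for j, locus in enumerate(g.loci):
            typed = idx[~missing[idx, j]]
            n_typed[(pop, locus)] = len(typed)
            if len(typed) == 0:
                continue
            alleles, counts = np.unique(g.calls[typed, j, :], return_counts=True)
            total = counts.sum()
            freqs[(pop, locus)] = {
                int(a): c / total for a, c in zip(alleles, counts)
            }
    return AlleleFrequencies(freqs, n_typed, g.subpopulations, list(g.loci))


# -- diversity ----------------------------------------------------------------


@dataclass
class DiversitySummary:
    """Per-(subpopulation, locus) diversity table plus across-locus means."""

    per_locus: pd.DataFrame  # columns: subpopulation, locus, N, Na, Ne, Ho, He, uHe, I, F
    by_subpop: pd.DataFrame  # means ± SE across loci, plus P (% polymorphic)


def _locus_diversity(
    g: GenotypeTable, pop: str, locus: str, af: AlleleFrequencies
) -> Optional[dict]:
    key = (pop, locus)
    n = af.n_typed.get(key, 0)
    if n == 0:
        return None
    p = np.array(list(af.freqs[key].values()))
    sum_p2 = float((p**2).sum())
    he = 1.0 - sum_p2
    uhe = he * (2 * n) / (2 * n - 1) if n > 0 else float("nan")
    j = g.loci.index(locus)
    idx = g.pop_indices(pop)
    missing = g.is_missing()
    typed = idx[~missing[idx, j]]
    calls = g.calls[typed, j, :]
    ho = float((calls[:, 0] != calls[:, 1]).mean())
    shannon = float(-(p * np.log(p)).sum())
    f = 1.0 - ho / he if he > 0 else float("nan")
    return {
        "subpopulation": pop,
        "locus": locus,
        "N": n,
        "Na": len(p),
        "Ne": 1.0 / sum_p2,
        "Ho": ho,
        "He": he,
        "uHe": uhe,
        "I": shannon,
        "F": f,
    }


def diversity(g: GenotypeTable) -> DiversitySummary:
    """Standard per-subpopulation diversity summary.

    He = 1 − Σp²; uHe applies the 2N/(2N−1) small-sample correction;
    Ne (effective alleles) = 1/Σp²; I is Shannon's index; F = 1 − Ho/He,
    excluded from across-locus means at monomorphic loci (He = 0).
    """
    af = allele_frequencies(g)
    rows = []
    for pop in g.subpopulations:
        for locus in g.loci:
            r = _locus_diversity(g, pop, locus, af)
            if r is not None:
                rows.append(r)
    per_locus = pd.DataFrame(rows)
    summaries = []
    for pop in g.subpopulations:
        sub = per_locus[per_locus["subpopulation"] == pop]
        if sub.empty:
            continue
        entry: dict = {"subpopulation": pop, "N": float(sub["N"].mean())}
        for col in ("Na", "Ne", "Ho", "He", "uHe", "I", "F"):
            vals = sub[col].dropna()
            entry[col] = float(vals.mean()) if len(vals) else float("nan")
            entry[f"{col}_se"] = (
                float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        entry["P"] = 100.0 * float((sub["Na"] >= 2).mean())
        summaries.append(entry)
    return DiversitySummary(per_locus=per_locus, by_subpop=pd.DataFrame(summaries))


def pic(freqs: Sequence[float] | dict[int, float]) -> float:
    """Polymorphism information content (Botstein et al. 1980).

    PIC = 1 − Σpᵢ² − Σ_{i<j} 2 pᵢ² pⱼ², from pooled allele frequencies.
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else freqs, float)
    if p.size == 0:
        raise ValueError("need at least one allele")
    sum_p2 = float((p**2).sum())
    # Σ_{i<j} 2 pᵢ²pⱼ² = (Σp²)² − Σp⁴
    cross = float(sum_p2**2 - (p**4).sum())
    return 1.0 - sum_p2 - cross


# -- Hardy-Weinberg -----------------------------------------------------------


def hwe_chisq(g: GenotypeTable, subpopulation: str, locus: str) -> dict:
    """Chi-square goodness-of-fit test against Hardy–Weinberg proportions.

    Expected genotype counts come from the sample allele frequencies;
    df = k(k−1)/2 for k alleles. A warning flag is set when any expected
    count falls below 5 (the chi-square approximation is then poor).
    """
    j = g.loci.index(locus)
    idx = g.pop_indices(subpopulation)
    missing = g.is_missing()
    typed = idx[~missing[idx, j]]
    if len(typed) == 0:
        raise ValueError(f"locus {locus} untyped in {subpopulation}")
    calls = np.sort(g.calls[typed, j, :], axis=1)
    alleles = sorted(set(calls.ravel().tolist()))
    k = len(alleles)
    if k < 2:
        return {
            "chi2": float("nan"),
            "df": 0,
            "p": float("nan"),
            "testable": False,
            "low_expected": False,
        }
    n = len(typed)
    counts = np.zeros(2 * n)
    freq = {
        a: float((calls == a).sum()) / (2 * n) for a in alleles
    }
    observed: dict[tuple[int, int], int] = {}
    for a, b in calls:
        observed[(int(a), int(b))] = observed.get((int(a), int(b)), 0) + 1
    chi2 = 0.0
    low = False
    for ai in range(k):
        for bi in range(ai, k):
            a, b = alleles[ai], alleles[bi]
            exp = n * (freq[a] ** 2 if a == b else 2 * freq[a] * freq[b])
            obs = observed.get((a, b), 0)
            if exp < 5:
                low = True
            if exp > 0:
                chi2 += (obs - exp) ** 2 / exp
    df = k * (k - 1) // 2
    return {
        "chi2": chi2,
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)),
        "testable": True,
        "low_expected": low,
    }


# -- F-statistics (Nei 1977 decomposition) ------------------------------------


@dataclass
class FStatistics:
    """Per-locus and mean fixation indices with permutation p-values."""

    per_locus: pd.DataFrame  # locus, Ho, Hs, Ht, FIS, FST, FIT
    mean: dict[str, float]
    p_fst: Optional[float] = None
    p_fis: Optional[float] = None


def _nei_components(g: GenotypeTable, locus: str) -> Optional[dict]:
    """Mean Ho, Hs (mean subpop He) and Ht (He of mean freqs) at a locus."""
    af = allele_frequencies(g)
    j = g.loci.index(locus)
    missing = g.is_missing()
    hos, hes, profiles = [], [], []
    alleles = af.alleles(locus)
    for pop in g.subpopulations:
        key = (pop, locus)
        if af.n_typed.get(key, 0) == 0:
            continue
        idx = g.pop_indices(pop)
        typed = idx[~missing[idx, j]]
        calls = g.calls[typed, j, :]
        hos.append(float((calls[:, 0] != calls[:, 1]).mean()))
        p = np.array([af.freqs[key].get(a, 0.0) for a in alleles])
        hes.append(1.0 - float((p**2).sum()))
        profiles.append(p)
    if len(profiles) < 2:
        return None
    pbar = np.mean(profiles, axis=0)  # unweighted mean across subpopulations
    ht = 1.0 - float((pbar**2).sum())
    return {"Ho": float(np.mean(hos)), "Hs": float(np.mean(hes)), "Ht": ht}


def f_statistics(
    g: GenotypeTable, n_permutations: int = 999, seed: Optional[int] = None
) -> FStatistics:
    """Wright's FIS/FST/FIT via the Nei (1977) decomposition.

    Hs is the unweighted mean of subpopulation expected heterozygosities and
    Ht the expected heterozygosity of the unweighted mean allele frequencies,
    so (1 − FIT) = (1 − FIS)(1 − FST) holds exactly per locus. Significance:
    FST by permuting individuals among subpopulations, FIS by permuting
    alleles among individuals within subpopulations, both with (b+1)/(m+1)
    smoothing.
    """
    rows = []
    for locus in g.loci:
        comp = _nei_components(g, locus)
        if comp is None or comp["Ht"] <= 0:
            continue
        ho, hs, ht = comp["Ho"], comp["Hs"], comp["Ht"]
        rows.append(
            {
                "locus": locus,
                "Ho": ho,
                "Hs": hs,
                "Ht": ht,
                "FIS": 1.0 - ho / hs if hs > 0 else float("nan"),
                "FST": 1.0 - hs / ht,
                "FIT": 1.0 - ho / ht,
            }
        )
    if not rows:
        raise ValueError("no locus with defined Ht")
    per_locus = pd.DataFrame(rows)
    mean = {
        k: float(per_locus[k].mean()) for k in ("Ho", "Hs", "Ht", "FIS", "FST", "FIT")
    }
    p_fst = p_fis = None
    if n_permutations >= 1:
        rng = np.random.default_rng(seed)
        obs_fst = mean["FST"]
        obs_fis = mean["FIS"]
        labels = [pop for _, pop in g.individuals]
        b_fst = b_fis = 0
        for _ in range(n_permutations):
            perm = g.with_labels(rng.permutation(labels).tolist())
            if _mean_stat(perm, "FST") >= obs_fst:
                b_fst += 1
            shuf = _shuffle_alleles_within_pops(g, rng)
            if _mean_stat(shuf, "FIS") >= obs_fis:
                b_fis += 1
        p_fst = (b_fst + 1) / (n_permutations + 1)
        p_fis = (b_fis + 1) / (n_permutations + 1)
    return FStatistics(per_locus=per_locus, mean=mean, p_fst=p_fst, p_fis=p_fis)


def _mean_stat(g: GenotypeTable, which: str) -> float:
    vals = []
    for locus in g.loci:
        comp = _nei_components(g, locus)
        if comp is None or comp["Ht"] <= 0:
            continue
        if which == "FST":
            if comp["Ht"] > 0:
                vals.append(1.0 - comp["Hs"] / comp["Ht"])
        elif which == "FIS":
            if comp["Hs"] > 0:
                vals.append(1.0 - comp["Ho"] / comp["Hs"])
    return float(np.mean(vals)) if vals else float("nan")


def _shuffle_alleles_within_pops(
    g: GenotypeTable, rng: np.random.Generator
) -> GenotypeTable:
    """Randomise allele pairing within each subpopulation at each locus."""
    calls = g.calls.copy()
    missing = g.is_missing()
    for pop in g.subpopulations:
        idx = g.pop_indices(pop)
        for j in range(g.n_loci):
            typed = idx[~missing[idx, j]]
            if len(typed) < 2:
                continue
            pool = calls[typed, j, :].ravel()
            rng.shuffle(pool)
            calls[typed, j, :] = pool.reshape(-1, 2)
    return GenotypeTable(g.individuals, g.loci, calls)


# -- Nei distance & gene flow -------------------------------------------------


def nei_unbiased_distance(
    g: GenotypeTable, floor: float = 1e-6
) -> pd.DataFrame:
    """Nei (1978) unbiased genetic distance between all subpopulation pairs.

    Within-population identities use the bias correction
    (2N Σp² − 1)/(2N − 1); identities are averaged over loci before taking
    the log. Tiny negative corrected identities are floored at ``floor``
    with a warning. No shared alleles at any locus gives infinite distance.
    """
    af = allele_frequencies(g)
    pops = g.subpopulations
    D = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, px in enumerate(pops):
        for qy in pops[i + 1 :]:
            jxy, jx, jy, n_loci = 0.0, 0.0, 0.0, 0
            for locus in g.loci:
                kx, ky = (px, locus), (qy, locus)
                nx, ny = af.n_typed.get(kx, 0), af.n_typed.get(ky, 0)
                if nx == 0 or ny == 0:
                    continue
                alleles = af.alleles(locus)
                fx = np.array([af.freqs[kx].get(a, 0.0) for a in alleles])
                fy = np.array([af.freqs[ky].get(a, 0.0) for a in alleles])
                jxy += float((fx * fy).sum())
                jx += (2 * nx * float((fx**2).sum()) - 1) / (2 * nx - 1)
                jy += (2 * ny * float((fy**2).sum()) - 1) / (2 * ny - 1)
                n_loci += 1
            if n_loci == 0:
                D.loc[px, qy] = D.loc[qy, px] = float("nan")
                continue
            jxy, jx, jy = jxy / n_loci, jx / n_loci, jy / n_loci
            for name, val in (("Jx", jx), ("Jy", jy)):
                if val <= 0:
                    logger.warning(
                        "%s-%s: corrected identity %s=%.3g floored at %g",
                        px, qy, name, val, floor,
                    )
            jx, jy = max(jx, floor), max(jy, floor)
            if jxy <= 0:
                d = float("inf")
            else:
                d = -math.log(jxy / math.sqrt(jx * jy))
            D.loc[px, qy] = D.loc[qy, px] = d
    return D


def gene_flow(fst: float) -> float:
    """Wright's island-model migrant estimate Nm = (1 − FST)/(4 FST)."""
    if not 0.0 < fst <= 1.0:
        raise ValueError(f"FST must lie in (0, 1], got {fst}")
    return (1.0 - fst) / (4.0 * fst)


# -- null alleles & ENA-corrected FST -----------------------------------------


@dataclass
class NullAlleleEstimates:
    """EM null-allele frequency estimates per (subpopulation, locus)."""

    r_hat: dict[tuple[str, str], float]
    iterations: dict[tuple[str, str], int] = field(default_factory=dict)
    converged: dict[tuple[str, str], bool] = field(default_factory=dict)
    visible_freqs: dict[tuple[str, str], dict[int, float]] = field(
        default_factory=dict
    )


def null_allele_em(
    g: GenotypeTable,
    subpopulation: str,
    locus: str,
    tol: float = 1e-7,
    max_iter: int = 20_000,
) -> tuple[float, dict[int, float], int, bool]:
    """EM estimate of the null-allele frequency at one (subpopulation, locus).

    Model: Hardy–Weinberg with one unamplifiable allele of frequency r.
    Observed visible homozygotes are a mixture of true homozygotes and
    visible/null heterozygotes; blank (missing) genotypes are null/null.
    Returns ``(r_hat, visible_freqs, iterations, converged)`` where
    ``visible_freqs`` are the EM-estimated true frequencies of the visible
    alleles (summing to 1 − r_hat).
    """
    j = g.loci.index(locus)
    idx = g.pop_indices(subpopulation)
    if len(idx) == 0:
        raise ValueError(f"no individuals in {subpopulation}")
    missing = g.is_missing()
    typed = idx[~missing[idx, j]]
    n_blank = len(idx) - len(typed)
    if len(typed) == 0:
        return 1.0, {}, 0, True  # boundary: everything blank
    calls = np.sort(g.calls[typed, j, :], axis=1)
    alleles = sorted(set(calls.ravel().tolist()))
    if len(alleles) == 1 and n_blank == 0:
        # single visible allele, no blanks: likelihood (1 - r^2)^n peaks at r = 0
        return 0.0, {alleles[0]: 1.0}, 0, True
    het_mask = calls[:, 0] != calls[:, 1]
    hom_counts = {
        a: int(((calls[:, 0] == a) & ~het_mask).sum()) for a in alleles
    }
    het_counts: dict[int, int] = {a: 0 for a in alleles}
    for a, b in calls[het_mask]:
        het_counts[int(a)] += 1
        het_counts[int(b)] += 1
    n_total = len(idx)
    # init: observed allele shares scaled by a small null frequency
    r = max(math.sqrt(n_blank / n_total), 0.05) if n_total else 0.05
    counts_obs = {a: float((calls == a).sum()) for a in alleles}
    total_obs = sum(counts_obs.values())
    p = {a: (1 - r) * counts_obs[a] / total_obs for a in alleles}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = {a: float(het_counts[a]) for a in alleles}
        null_count = 2.0 * n_blank
        for a in alleles:
            if hom_counts[a] == 0:
                continue
            denom = p[a] + 2.0 * r
            w = p[a] / denom if denom > 0 else 1.0  # P(true homozygote)
            counts[a] += hom_counts[a] * (1.0 + w)
            null_count += hom_counts[a] * (1.0 - w)
        total = sum(counts.values()) + null_count
        new_p = {a: c / total for a, c in counts.items()}
        new_r = null_count / total
        delta = abs(new_r - r) + sum(abs(new_p[a] - p[a]) for a in alleles)
        p, r = new_p, new_r
        if delta < tol:
            converged = True
            break
    return r, p, it, converged


def estimate_null_alleles(
    g: GenotypeTable, tol: float = 1e-7, max_iter: int = 20_000
) -> NullAlleleEstimates:
    """Run the null-allele EM over every (subpopulation, locus) cell."""
    est = NullAlleleEstimates(r_hat={})
    for pop in g.subpopulations:
        for locus in g.loci:
            try:
                r, p, it, conv = null_allele_em(g, pop, locus, tol, max_iter)
            except ValueError:
                continue
            key = (pop, locus)
            est.r_hat[key] = r
            est.visible_freqs[key] = p
            est.iterations[key] = it
            est.converged[key] = conv
            if not conv:
                logger.warning("null-allele EM did not converge for %s", key)
    return est


def _wc_theta_components(
    pop_freqs: list[dict[int, float]],
    pop_sizes: list[int],
    pop_het: list[dict[int, float]],
) -> tuple[float, float]:
    """Weir & Cockerham (1984) per-locus numerator and denominator sums.

    ``pop_het[i][a]`` is the frequency of individuals in population i that
    are heterozygous and carry allele a.
    """
    r = len(pop_sizes)
    if r < 2:
        return 0.0, 0.0
    n = np.asarray(pop_sizes, dtype=float)
    nbar = n.mean()
    if nbar <= 1:
        return 0.0, 0.0
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted({a for f in pop_freqs for a in f})
    num = den = 0.0
    for a in alleles:
        p = np.array([f.get(a, 0.0) for f in pop_freqs])
        h = np.array([hh.get(a, 0.0) for hh in pop_het])
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a_comp = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b_comp = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c_comp = hbar / 2.0
        num += a_comp
        den += a_comp + b_comp + c_comp
    return num, den


def _wc_locus_inputs(g: GenotypeTable, locus: str):
    af = allele_frequencies(g)
    j = g.loci.index(locus)
    missing = g.is_missing()
    pop_freqs, pop_sizes, pop_het = [], [], []
    for pop in g.subpopulations:
        key = (pop, locus)
        n = af.n_typed.get(key, 0)
        if n == 0:
            continue
        idx = g.pop_indices(pop)
        typed = idx[~missing[idx, j]]
        calls = g.calls[typed, j, :]
        het = calls[:, 0] != calls[:, 1]
        hd: dict[int, float] = {}
        for a in set(calls.ravel().tolist()):
            carries = het & ((calls[:, 0] == a) | (calls[:, 1] == a))
            hd[int(a)] = float(carries.mean())
        pop_freqs.append(af.freqs[key])
        pop_sizes.append(n)
        pop_het.append(hd)
    return pop_freqs, pop_sizes, pop_het


def weir_cockerham_fst(g: GenotypeTable) -> tuple[float, dict[str, float]]:
    """Multi-locus Weir & Cockerham (1984) theta, plus per-locus values."""
    num = den = 0.0
    per_locus = {}
    for locus in g.loci:
        a, d = _wc_theta_components(*_wc_locus_inputs(g, locus))
        if d != 0:
            per_locus[locus] = a / d
        num += a
        den += d
    if den == 0:
        raise ValueError("theta undefined: no variation")
    return num / den, per_locus


def fst_ena(
    g: GenotypeTable,
    n_bootstrap: int = 10_000,
    seed: Optional[int] = None,
    null_estimates: Optional[NullAlleleEstimates] = None,
) -> dict:
    """Null-allele-corrected (ENA) and uncorrected Weir–Cockerham FST.

    The "excluding null alleles" correction estimates, per (subpopulation,
    locus), the true visible-allele frequencies with the EM algorithm and
    computes theta over the visible alleles only, on those frequencies
    *without* renormalisation. Renormalising would divide every visible
    frequency by 1 − r̂ and thereby re-inject the very between-population
    noise in the null frequency that inflates the apparent FST; leaving the
    frequencies on the full-simplex scale removes that inflation. Because
    individual-level corrected genotypes are unobservable, the
    heterozygosity entering the corrected estimator is its Hardy–Weinberg
    expectation under the EM frequencies. Bootstrap over loci gives
    percentile CIs.
    """
    if len(g.subpopulations) < 2:
        raise ValueError("need >= 2 subpopulations")
    est = null_estimates or estimate_null_alleles(g)
    raw: dict[str, tuple[float, float]] = {}
    corr: dict[str, tuple[float, float]] = {}
    for locus in g.loci:
        raw[locus] = _wc_theta_components(*_wc_locus_inputs(g, locus))
        pop_freqs, pop_sizes, pop_het = [], [], []
        af = allele_frequencies(g)
        for pop in g.subpopulations:
            key = (pop, locus)
            n = af.n_typed.get(key, 0)
            if n == 0:
                continue
            vis = est.visible_freqs.get(key)
            r = est.r_hat.get(key, 0.0)
            if vis and r < 1.0 and sum(vis.values()) > 0:
                freqs = dict(vis)  # sums to 1 - r̂: null excluded, no renormalisation
            else:
                freqs = af.freqs[key]
            visible_total = sum(freqs.values())
            het = {a: 2 * pa * (visible_total - pa) for a, pa in freqs.items()}
            pop_freqs.append(freqs)
            pop_sizes.append(n)
            pop_het.append(het)
        corr[locus] = _wc_theta_components(pop_freqs, pop_sizes, pop_het)

    def ratio(components: dict[str, tuple[float, float]], loci) -> float:
        num = sum(components[lc][0] for lc in loci)
        den = sum(components[lc][1] for lc in loci)
        return num / den if den != 0 else float("nan")

    loci = list(g.loci)
    result = {
        "fst_uncorrected": ratio(raw, loci),
        "fst_corrected": ratio(corr, loci),
        "per_locus_uncorrected": {
            lc: (raw[lc][0] / raw[lc][1] if raw[lc][1] else float("nan")) for lc in loci
        },
        "per_locus_corrected": {
            lc: (corr[lc][0] / corr[lc][1] if corr[lc][1] else float("nan"))
            for lc in loci
        },
        "null_r_hat": dict(est.r_hat),
    }
    if n_bootstrap < 1:
        return result
    if len(loci) < 2:
        logger.warning("single locus: bootstrap CI is degenerate")
        result["ci_uncorrected"] = (result["fst_uncorrected"],) * 2
        result["ci_corrected"] = (result["fst_corrected"],) * 2
        return result
    rng = np.random.default_rng(seed)
    boots_raw, boots_corr = [], []
    for _ in range(n_bootstrap):
        sample = rng.choice(loci, size=len(loci), replace=True)
        boots_raw.append(ratio(raw, sample))
        boots_corr.append(ratio(corr, sample))
    result["ci_uncorrected"] = tuple(np.nanpercentile(boots_raw, [2.5, 97.5]))
    result["ci_corrected"] = tuple(np.nanpercentile(boots_corr, [2.5, 97.5]))
    return result


# -- AMOVA --------------------------------------------------------------------


@dataclass
class AmovaResult:
    """Two-level AMOVA decomposition with permutation significance."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: Optional[float]
    negative_component_truncated: bool = False


def _genotype_distance_matrix(g: GenotypeTable) -> np.ndarray:
    """Pairwise squared distances: non-shared alleles per locus, summed.

    The allele-mismatch (infinite-allele) metric: per locus, the diploid
    genotypes {a,b} and {c,d} differ by 2 − |multiset intersection|. Loci
    missing in either individual are skipped for that pair.
    """
    n = g.n_individuals
    missing = g.is_missing()
    D = np.zeros((n, n))
    sorted_calls = np.sort(g.calls, axis=2)
    for i in range(n):
        for k in range(i + 1, n):
            d = 0.0
            for j in range(g.n_loci):
                if missing[i, j] or missing[k, j]:
                    continue
                a, b = sorted_calls[i, j]
                c, e = sorted_calls[k, j]
                shared = 0
                # multiset intersection of two unordered pairs
                remaining = [c, e]
                for allele in (a, b):
                    if allele in remaining:
                        remaining.remove(allele)
                        shared += 1
                d += 2 - shared
            D[i, k] = D[k, i] = d
    return D


def _amova_from_distances(
    D: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float, float, bool]:
    """SS decomposition and variance components from a squared-distance matrix."""
    n = len(labels)
    pops, counts = np.unique(labels, return_counts=True)
    ss_total = D[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for pop, n_p in zip(pops, counts):
        idx = np.where(labels == pop)[0]
        sub = D[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / n_p
    ss_among = ss_total - ss_within
    df_among = len(pops) - 1
    df_within = n - len(pops)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (counts**2).sum() / n) / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    truncated = False
    if var_among < 0:
        var_among = 0.0
        truncated = True
    return ss_among, ss_within, var_among, var_within, ms_among, truncated


def amova(
    g: GenotypeTable, n_permutations: int = 9999, seed: Optional[int] = None
) -> AmovaResult:
    """Two-level AMOVA (among vs within subpopulations).

    Distances are allele-mismatch counts between diploid multilocus
    genotypes. Significance: fraction of subpopulation-label permutations
    with Phi_ST at least the observed, with (b+1)/(m+1) smoothing.
    Subpopulations with fewer than 2 individuals are excluded.
    """
    keep = [
        i
        for i, (_, pop) in enumerate(g.individuals)
        if len(g.pop_indices(pop)) >= 2
    ]
    if len(keep) < g.n_individuals:
        logger.warning("AMOVA: excluding subpopulations with < 2 individuals")
        g = g.subset(keep)
    if len(g.subpopulations) < 2:
        raise ValueError("AMOVA needs >= 2 subpopulations with >= 2 individuals")
    D = _genotype_distance_matrix(g)
    labels = np.array([pop for _, pop in g.individuals])
    ss_a, ss_w, var_a, var_w, _, truncated = _amova_from_distances(D, labels)
    total_var = var_a + var_w
    phi = var_a / total_var if total_var > 0 else 0.0
    n_pops = len(np.unique(labels))
    p_value = None
    if n_permutations >= 1:
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            _, _, va, vw, _, _ = _amova_from_distances(D, perm)
            tot = va + vw
            phi_perm = va / tot if tot > 0 else 0.0
            if phi_perm >= phi:
                b += 1
        p_value = (b + 1) / (n_permutations + 1)
    return AmovaResult(
        df_among=n_pops - 1,
        df_within=len(labels) - n_pops,
        ss_among=ss_a,
        ss_within=ss_w,
        var_among=var_a,
        var_within=var_w,
        pct_among=100.0 * phi,
        pct_within=100.0 * (1 - phi),
        phi_st=phi,
        p_value=p_value,
        negative_component_truncated=truncated,
    )


# -- PCoA ---------------------------------------------------------------------


def pcoa(distance_matrix: np.ndarray | pd.DataFrame) -> dict:
    """Principal coordinates analysis by Gower double-centring.

    Axes are ordered by eigenvalue; axes with negative eigenvalues (possible
    for non-Euclidean distances) are reported but carry no coordinates.
    """
    names = None
    if isinstance(distance_matrix, pd.DataFrame):
        names = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total = eigval[pos].sum()
    pct = (eigval[pos] / total * 100.0) if total > 0 else eigval[pos] * 0.0
    return {
        "coordinates": coords,
        "eigenvalues": eigval,
        "pct_variance": pct,
        "names": names,
    }


# -- Evanno delta-K -----------------------------------------------------------


def evanno_delta_k(lnp_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno et al. ΔK from replicate clustering log-probabilities.

    Input: columns ``K`` and ``lnp`` (one row per replicate run). For each
    interior K, ΔK = mean(|L(K+1) − 2 L(K) + L(K−1)|) / sd(L(K)), with
    replicates paired by their order within each K when counts allow,
    otherwise using means. Requires ≥3 consecutive K values and ≥2
    replicates per K; zero sd leaves ΔK undefined (flagged NaN).
    """
    grp = lnp_table.groupby("K")["lnp"]
    ks = sorted(grp.groups)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValueError("K values must be consecutive")
    counts = grp.count()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per K for sd")
    means = grp.mean()
    sds = grp.std(ddof=1)
    paired = counts.nunique() == 1
    reps = {k: np.sort(grp.get_group(k).to_numpy()) for k in ks}
    rows = []
    for k in ks:
        row = {
            "K": k,
            "mean_lnp": float(means[k]),
            "sd_lnp": float(sds[k]),
            "delta_k": float("nan"),
            "sd_zero": False,
        }
        if ks[0] < k < ks[-1]:
            if paired:
                second = np.abs(reps[k + 1] - 2 * reps[k] + reps[k - 1])
                num = float(second.mean())
            else:
                num = abs(float(means[k + 1] - 2 * means[k] + means[k - 1]))
            if sds[k] > 0:
                row["delta_k"] = num / float(sds[k])
            else:
                row["sd_zero"] = True
                row["delta_k"] = 0.0 if num == 0 else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    interior = out["delta_k"].dropna()
    out.attrs["best_k"] = (
        int(out.loc[interior.idxmax(), "K"]) if len(interior) else None
    )
    return out
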