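"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with plain loops, dictionaries and
textbook formulas, sharing no code path with the package, so agreement
between the two is meaningful evidence of correctness.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


# -- geometry ------------------------------------------------------------------


def hull_area_bruteforce(points) -> float:
    """Convex-hull area by O(n^3) edge testing plus the shoelace formula.

    A directed segment (p, q) is a hull edge iff every other point lies on or
    to the left of it; walking those edges yields the hull polygon. Degenerate
    sets (all collinear, or fewer than 3 distinct points) have area 0.
    """
    pts = sorted(set((float(x), float(y)) for x, y in points))
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    edges = {}
    for p in pts:
        for q in pts:
            if p == q:
                continue
            left_ok = True
            strictly_left = False
            for r in pts:
                if r == p or r == q:
                    continue
                c = cross(p, q, r)
                if c < -1e-9:
                    left_ok = False
                    break
                if c > 1e-9:
                    strictly_left = True
            if left_ok and strictly_left:
                # keep the farthest q for collinear chains along the edge
                if p not in edges or (
                    (q[0] - p[0]) ** 2 + (q[1] - p[1]) ** 2
                    > (edges[p][0] - p[0]) ** 2 + (edges[p][1] - p[1]) ** 2
                ):
                    edges[p] = q
    if not edges:
        return 0.0  # collinear
    start = min(edges)
    poly = [start]
    cur = edges[start]
    while cur != start and len(poly) <= len(pts):
        poly.append(cur)
        cur = edges.get(cur)
        if cur is None:
            return 0.0
    area = 0.0
    for i in range(len(poly)):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % len(poly)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def aoo_bruteforce(points, cell_km=1.0, origin=(0.0, 0.0)):
    """Occupied-cell count by exhaustive enumeration over the bounding box."""
    ox, oy = origin
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    i_lo = math.floor((min(xs) - ox) / cell_km) - 1
    i_hi = math.floor((max(xs) - ox) / cell_km) + 1
    j_lo = math.floor((min(ys) - oy) / cell_km) - 1
    j_hi = math.floor((max(ys) - oy) / cell_km) + 1
    occupied = set()
    for i in range(i_lo, i_hi + 1):
        for j in range(j_lo, j_hi + 1):
            x0, y0 = ox + i * cell_km, oy + j * cell_km
            for x, y in points:
                if x0 <= x < x0 + cell_km and y0 <= y < y0 + cell_km:
                    occupied.add((i, j))
                    break
    return len(occupied)


def haversine_km(lon1, lat1, lon2, lat2, radius_km):
    """Great-circle distance on a sphere."""
    f1, f2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    df = f2 - f1
    a = math.sin(df / 2) ** 2 + math.cos(f1) * math.cos(f2) * math.sin(dl / 2) ** 2
    return 2 * radius_km * math.asin(math.sqrt(a))


# -- genotype bookkeeping ------------------------------------------------------


def _typed_genotypes(genotypes):
    """Drop genotypes containing the missing code 0."""
    return [(a, b) for a, b in genotypes if a != 0 and b != 0]


def allele_counts(genotypes) -> Counter:
    c: Counter = Counter()
    for a, b in _typed_genotypes(genotypes):
        c[a] += 1
        c[b] += 1
    return c


def allele_freqs(genotypes) -> dict:
    c = allele_counts(genotypes)
    tot = sum(c.values())
    return {a: k / tot for a, k in c.items()}


def diversity_oracle(genotypes) -> dict:
    """N, Na, Ne, Ho, He, uHe, I, F for one (subpopulation, locus) sample."""
    typed = _typed_genotypes(genotypes)
    n = len(typed)
    p = allele_freqs(genotypes)
    sum_p2 = sum(v * v for v in p.values())
    he = 1.0 - sum_p2
    ho = sum(1 for a, b in typed if a != b) / n
    return {
        "N": n,
        "Na": len(p),
        "Ne": 1.0 / sum_p2,
        "Ho": ho,
        "He": he,
        "uHe": he * 2 * n / (2 * n - 1),
        "I": -sum(v * math.log(v) for v in p.values()),
        "F": (1.0 - ho / he) if he > 0 else float("nan"),
    }


def nei_fstats_oracle(pops_genotypes) -> dict:
    """Ho, Hs, Ht, FIS, FST, FIT for one locus from per-pop genotype lists.

    Hs = unweighted mean subpopulation expected heterozygosity; Ht = expected
    heterozygosity of the unweighted mean allele-frequency vector.
    """
    hos, hes, freq_vectors = [], [], []
    for genotypes in pops_genotypes:
        typed = _typed_genotypes(genotypes)
        if not typed:
            continue
        hos.append(sum(1 for a, b in typed if a != b) / len(typed))
        p = allele_freqs(genotypes)
        hes.append(1.0 - sum(v * v for v in p.values()))
        freq_vectors.append(p)
    alleles = sorted({a for p in freq_vectors for a in p})
    r = len(freq_vectors)
    pbar = {a: sum(p.get(a, 0.0) for p in freq_vectors) / r for a in alleles}
    ht = 1.0 - sum(v * v for v in pbar.values())
    ho = sum(hos) / len(hos)
    hs = sum(hes) / len(hes)
    return {
        "Ho": ho,
        "Hs": hs,
        "Ht": ht,
        "FIS": 1.0 - ho / hs,
        "FST": 1.0 - hs / ht,
        "FIT": 1.0 - ho / ht,
    }


def nei_unbiased_distance_oracle(genx_by_locus, geny_by_locus) -> float:
    """Nei (1978) unbiased D between two populations, direct formula."""
    jxy = jx = jy = 0.0
    n_loci = 0
    for gx, gy in zip(genx_by_locus, geny_by_locus):
        tx, ty = _typed_genotypes(gx), _typed_genotypes(gy)
        if not tx or not ty:
            continue
        nx, ny = len(tx), len(ty)
        px, py = allele_freqs(gx), allele_freqs(gy)
        alleles = set(px) | set(py)
        jxy += sum(px.get(a, 0.0) * py.get(a, 0.0) for a in alleles)
        jx += (2 * nx * sum(v * v for v in px.values()) - 1) / (2 * nx - 1)
        jy += (2 * ny * sum(v * v for v in py.values()) - 1) / (2 * ny - 1)
        n_loci += 1
    jxy, jx, jy = jxy / n_loci, jx / n_loci, jy / n_loci
    return -math.log(jxy / math.sqrt(jx * jy))


def genotype_distance_oracle(ind1, ind2) -> float:
    """Squared allele-mismatch distance between two multilocus genotypes."""
    d = 0.0
    for (a, b), (c, e) in zip(ind1, ind2):
        if 0 in (a, b, c, e):
            continue
        shared = sum((Counter([a, b]) & Counter([c, e])).values())
        d += 2 - shared
    return d


def amova_oracle(pops_multilocus) -> dict:
    """Two-level AMOVA from per-pop lists of multilocus genotypes.

    Sums of squares via the pairwise-distance identity
    SS = (1/n) Σ_{i<j} d²ᵢⱼ within each grouping.
    """
    individuals = [ind for pop in pops_multilocus for ind in pop]
    labels = [k for k, pop in enumerate(pops_multilocus) for _ in pop]
    n = len(individuals)
    npops = len(pops_multilocus)
    ss_total = sum(
        genotype_distance_oracle(individuals[i], individuals[j])
        for i, j in combinations(range(n), 2)
    ) / n
    ss_within = 0.0
    for k, pop in enumerate(pops_multilocus):
        idx = [i for i in range(n) if labels[i] == k]
        ss_within += sum(
            genotype_distance_oracle(individuals[i], individuals[j])
            for i, j in combinations(idx, 2)
        ) / len(idx)
    ss_among = ss_total - ss_within
    df_among = npops - 1
    df_within = n - npops
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    counts = [len(pop) for pop in pops_multilocus]
    n0 = (n - sum(c * c for c in counts) / n) / df_among
    var_within = ms_within
    var_among = max((ms_among - ms_within) / n0, 0.0)
    phi = var_among / (var_among + var_within)
    return {
        "ss_among": ss_among,
        "ss_within": ss_within,
        "var_among": var_among,
        "var_within": var_within,
        "phi_st": phi,
    }


# -- branching process ---------------------------------------------------------


def galton_watson_extinction(m: float, generations: int) -> list:
    """Extinction probability by generation t for Poisson(m) offspring, N0=1.

    q(0) = 0; q(t+1) = exp(m (q(t) - 1)) — the probability-generating-function
    recursion for a Galton–Watson process.
    """
    q = 0.0
    out = [q]
    for _ in range(generations):
        q = math.exp(m * (q - 1.0))
        out.append(q)
    return out
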