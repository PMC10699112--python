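"""Pairwise molecular-evolution statistics for ortholog codon alignments.

Implements the Nei–Gojobori (1986) counting estimator of synonymous and
nonsynonymous substitution rates with Jukes–Cantor multiple-hit correction,
a codon-column bootstrap Z-test for purifying selection, Rosner's
generalized extreme Studentized deviate (GESD) outlier scan, a
Mann–Whitney rank comparison, and the per-species phase-comparison driver
that strings them together.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA = dict(_TABLE.forward_table)

__all__ = [
    "OrthologPair",
    "CodonAlignmentPair",
    "DnDsEstimate",
    "SelectionTest",
    "OutlierScan",
    "RankComparison",
    "SaturationError",
    "filter_orthologs",
    "ng86_codon_sites",
    "ng86_pair",
    "codon_z_test",
    "gesd_outliers",
    "mann_whitney",
    "compare_phase_evolution",
]


class SaturationError(ValueError):
    """Raised when pS or pN reaches the Jukes–Cantor saturation bound (0.75)."""


@dataclass(frozen=True)
class OrthologPair:
    """Metadata describing one ortholog pair between two species."""

    gene_a: str
    gene_b: str
    species: str
    orthology_type: str = "one-to-one"
    confidence: float = 1.0
    percent_identity: float = 100.0
    group_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two gap-aligned, in-frame coding sequences.

    Lengths must be equal and divisible by 3; gaps are '-' characters.
    Complete (gap-free) codons must not be stop codons.
    """

    seq_a: str
    seq_b: str
    meta: OrthologPair | None = None

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
        if len(a) % 3 != 0:
            raise ValueError(f"alignment length {len(a)} not divisible by 3")
        for seq, name in ((a, "seq_a"), (b, "seq_b")):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if "-" in codon:
                    continue
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"internal stop codon {codon} at position {i} in {name}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_columns(self) -> list[tuple[str, str]]:
        """Complete, unambiguous, gap-free codon columns (pairwise deletion)."""
        cols = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if any(ch not in _BASES for ch in ca + cb):
                continue
            cols.append((ca, cb))
        return cols


@dataclass(frozen=True)
class DnDsEstimate:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None  # None when dS == 0 (ratio undefined)

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


@dataclass(frozen=True)
class SelectionTest:
    Z: float
    prob: float
    n_boot: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.prob < 0.05


@dataclass(frozen=True)
class OutlierScan:
    R_stats: tuple[float, ...]
    lambdas: tuple[float, ...]
    n_outliers: int
    outlier_indices: tuple[int, ...]
    alpha: float
    k_max: int


@dataclass(frozen=True)
class RankComparison:
    U: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    method: str = "normal"


# ---------------------------------------------------------------------------
# Ortholog filtering
# ---------------------------------------------------------------------------

def filter_orthologs(
    pairs: Iterable[OrthologPair],
    identity_min_by_species: Mapping[str, float],
    require_one_to_one: bool = True,
    confidence_min: float = 1.0,
    identity_default: float | None = None,
) -> list[OrthologPair]:
    """Retain pairs meeting orthology-type, confidence and identity thresholds.

    ``identity_min_by_species`` maps species label to the minimum percent
    identity; species absent from the map fall back to ``identity_default``
    (an error if that is None).
    """
    kept = []
    for pair in pairs:
        if pair.species in identity_min_by_species:
            threshold = identity_min_by_species[pair.species]
        elif identity_default is not None:
            threshold = identity_default
        else:
            raise KeyError(
                f"no identity threshold for species {pair.species!r} and no default"
            )
        if require_one_to_one and pair.orthology_type != "one-to-one":
            continue
        if pair.confidence < confidence_min:
            continue
        if pair.percent_identity < threshold:
            continue
        kept.append(pair)
    return kept


# ---------------------------------------------------------------------------
# NG86 site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for a sense codon.

    At each position the synonymous fraction is counted over the single-base
    changes that do not create a stop codon; stop-creating changes are
    excluded from the denominator, so s + n = 3 exactly.
    """
    codon = codon.upper()
    if codon not in _AA:
        raise ValueError(f"not a sense codon of the standard code: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if _AA[mutant] == _AA[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two sense codons.

    Differences are partitioned by enumerating every ordering of the
    differing positions (1, 2 or 6 pathways) and averaging over the
    pathways whose intermediate codons are not stops.
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        current = codon_a
        path_syn = 0
        path_nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _AA[nxt] == _AA[current]:
                path_syn += 1
            else:
                path_nonsyn += 1
            current = nxt
        if not blocked:
            n_paths += 1
            syn_total += path_syn
            nonsyn_total += path_nonsyn
    if n_paths == 0:
        # All pathways pass through a stop. Fall back to classifying each
        # differing position as an independent change from codon_a.
        warnings.warn(
            f"all mutational pathways {codon_a}->{codon_b} pass through stop "
            "codons; classifying positions independently",
            RuntimeWarning,
            stacklevel=2,
        )
        syn = 0.0
        nonsyn = 0.0
        for pos in positions:
            step = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1 :]
            if step not in STOP_CODONS and _AA[step] == _AA[codon_a]:
                syn += 1.0
            else:
                nonsyn += 1.0
        return syn, nonsyn
    return syn_total / n_paths, nonsyn_total / n_paths


def _column_stats(alignment: CodonAlignmentPair) -> np.ndarray:
    """Per usable codon column: [s_sites, n_sites, syn_diffs, nonsyn_diffs].

    Sites are averaged over the two sequences. Columns containing gaps,
    ambiguity codes or stop codons are skipped (pairwise deletion).
    """
    rows = []
    for ca, cb in alignment.codon_columns():
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = ng86_codon_sites(ca)
        sb, nb = ng86_codon_sites(cb)
        sd, nd = _codon_pair_diffs(ca, cb)
        rows.append(((sa + sb) / 2.0, (na + nb) / 2.0, sd, nd))
    if not rows:
        raise ValueError("no usable codon columns after gap/ambiguity filtering")
    return np.asarray(rows, dtype=float)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 0.75; Jukes–Cantor undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(alignment: CodonAlignmentPair) -> DnDsEstimate:
    """NG86 estimate of dN, dS and omega for one codon alignment pair.

    Raises :class:`SaturationError` when pS or pN reaches 0.75.
    """
    cols = _column_stats(alignment)
    S, N, Sd, Nd = cols.sum(axis=0)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    omega = dN / dS if dS > 0 else None
    return DnDsEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega)


# ---------------------------------------------------------------------------
# Codon-based Z-test for purifying selection
# ---------------------------------------------------------------------------

def codon_z_test(
    alignment: CodonAlignmentPair,
    n_boot: int = 1000,
    seed: int = 0,
) -> SelectionTest:
    """One-tailed test of dN < dS with a codon-column bootstrap variance.

    Z = (dS - dN) / SE, where SE is the standard deviation of (dS - dN)
    over ``n_boot`` bootstrap resamples of codon columns; prob is the upper
    normal tail (small prob supports purifying selection).
    """
    if n_boot < 200:
        raise ValueError(f"n_boot must be >= 200, got {n_boot}")
    cols = _column_stats(alignment)
    n_cols = cols.shape[0]
    S, N, Sd, Nd = cols.sum(axis=0)
    if Sd == 0.0 and Nd == 0.0:
        warnings.warn("identical sequences: selection test has no signal", RuntimeWarning)
        return SelectionTest(Z=0.0, prob=1.0, n_boot=n_boot, seed=seed)
    d_obs = _jc_correct(Sd / S) - _jc_correct(Nd / N)

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cols, np.full(n_cols, 1.0 / n_cols), size=n_boot)
    totals = counts @ cols  # n_boot x 4
    with np.errstate(invalid="ignore", divide="ignore"):
        pS = totals[:, 2] / totals[:, 0]
        pN = totals[:, 3] / totals[:, 1]
        # resamples at/over the JC bound carry no usable distance; clip
        pS = np.clip(pS, 0.0, 0.7499999)
        pN = np.clip(pN, 0.0, 0.7499999)
        d_boot = -0.75 * (np.log1p(-4.0 * pS / 3.0) - np.log1p(-4.0 * pN / 3.0))
    se = float(np.std(d_boot, ddof=1))
    if se == 0.0 or not np.isfinite(se):
        warnings.warn("degenerate bootstrap resamples; prob set to 1", RuntimeWarning)
        return SelectionTest(Z=0.0, prob=1.0, n_boot=n_boot, seed=seed)
    z = d_obs / se
    prob = float(stats.norm.sf(z))
    return SelectionTest(Z=z, prob=prob, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Rosner's generalized ESD outlier scan
# ---------------------------------------------------------------------------

def gesd_outliers(
    values: Sequence[float],
    alpha: float = 0.05,
    k_max: int = 5,
) -> OutlierScan:
    """Rosner's generalized extreme Studentized deviate test.

    Iteratively removes the most extreme point and compares each deviate
    R_i against its critical value lambda_i; the declared outlier count is
    the largest i with R_i > lambda_i.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    if n < k_max + 3:
        raise ValueError(f"need n >= k_max + 3 (= {k_max + 3}), got n = {n}")
    remaining = x.copy()
    order = np.arange(n)
    R_stats: list[float] = []
    lambdas: list[float] = []
    removed: list[int] = []
    for i in range(1, k_max + 1):
        sd = remaining.std(ddof=1)
        if sd == 0.0:
            warnings.warn("zero variance; no outliers declarable", RuntimeWarning)
            break
        dev = np.abs(remaining - remaining.mean())
        j = int(np.argmax(dev))
        R_stats.append(float(dev[j] / sd))
        p = 1.0 - alpha / (2.0 * (n - i + 1))
        df = n - i - 1
        t = stats.t.ppf(p, df)
        lambdas.append(float((n - i) * t / math.sqrt((df + t * t) * (n - i + 1))))
        removed.append(int(order[j]))
        remaining = np.delete(remaining, j)
        order = np.delete(order, j)
    n_outliers = 0
    for i in range(len(R_stats), 0, -1):
        if R_stats[i - 1] > lambdas[i - 1]:
            n_outliers = i
            break
    return OutlierScan(
        R_stats=tuple(R_stats),
        lambdas=tuple(lambdas),
        n_outliers=n_outliers,
        outlier_indices=tuple(removed[:n_outliers]),
        alpha=alpha,
        k_max=k_max,
    )


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

_ALTERNATIVES = ("two_sided", "a_less", "a_greater")


def _exact_u_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Counts of each U value over all rank assignments (no ties)."""
    n = n_a + n_b
    counts = np.zeros(n_a * n_b + 1, dtype=np.int64)
    offset = n_a * (n_a + 1) // 2
    for combo in itertools.combinations(range(1, n + 1), n_a):
        counts[sum(combo) - offset] += 1
    return counts


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
    method: str = "auto",
) -> RankComparison:
    """Mann–Whitney U with midrank ties.

    With ``method="auto"``: exact enumeration when both samples have <= 8
    observations and there are no ties, otherwise normal approximation
    with tie and continuity corrections. ``method`` may force either path
    ("exact" requires no ties).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = xa.size, xb.size
    pooled = np.concatenate([xa, xb])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    use_exact = (
        method == "exact" or (method == "auto" and n_a <= 8 and n_b <= 8 and not has_ties)
    )
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free data")
    if use_exact:
        counts = _exact_u_distribution(n_a, n_b)
        total = counts.sum()
        ui = int(round(u))
        if alternative == "a_less":
            p = counts[: ui + 1].sum() / total
        elif alternative == "a_greater":
            p = counts[ui:].sum() / total
        else:
            lo, hi = min(ui, n_a * n_b - ui), max(ui, n_a * n_b - ui)
            p = (counts[: lo + 1].sum() + counts[hi:].sum()) / total
            p = min(1.0, p)
        method = "exact"
    else:
        n = n_a + n_b
        mu = n_a * n_b / 2.0
        tie_term = 0.0
        if has_ties:
            _, t = np.unique(pooled, return_counts=True)
            tie_term = float(np.sum(t**3 - t)) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "a_less":
                z = (u - mu + 0.5) / sd
                p = float(stats.norm.cdf(z))
            elif alternative == "a_greater":
                z = (u - mu - 0.5) / sd
                p = float(stats.norm.sf(z))
            else:
                z = (abs(u - mu) - 0.5) / sd
                z = max(z, 0.0)
                p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        method = "normal"
    return RankComparison(
        U=u,
        p_value=float(p),
        n_a=n_a,
        n_b=n_b,
        median_a=float(np.median(xa)),
        median_b=float(np.median(xb)),
        mean_a=float(np.mean(xa)),
        mean_b=float(np.mean(xb)),
        method=method,
    )


# ---------------------------------------------------------------------------
# Per-species phase comparison
# ---------------------------------------------------------------------------

@dataclass
class PhaseEvolutionReport:
    species: str
    n_a: int
    n_b: int
    mean_omega_a: float
    mean_omega_b: float
    median_omega_a: float
    median_omega_b: float
    U: float
    p_value: float
    n_outliers_a: int = 0
    n_outliers_b: int = 0
    dropped_a: int = 0
    dropped_b: int = 0


PairResult = tuple[OrthologPair, DnDsEstimate, "SelectionTest | None"]


def _usable_omegas(
    results: Iterable[PairResult],
    alpha: float,
    require_significant: bool,
) -> tuple[dict[str, list[float]], dict[str, int]]:
    omegas: dict[str, list[float]] = {}
    dropped: dict[str, int] = {}
    for pair, est, sel in results:
        sp = pair.species
        omegas.setdefault(sp, [])
        dropped.setdefault(sp, 0)
        if est.omega is None:
            dropped[sp] += 1
            continue
        if require_significant and (sel is None or sel.prob >= alpha):
            dropped[sp] += 1
            continue
        omegas[sp].append(est.omega)
    return omegas, dropped


def compare_phase_evolution(
    pairs_a: Sequence[PairResult],
    pairs_b: Sequence[PairResult],
    alpha: float = 0.05,
    require_significant: bool = True,
    gesd_alpha: float = 0.05,
    k_max: int = 5,
    alternative: str = "two_sided",
) -> list[PhaseEvolutionReport]:
    """Compare omega distributions of two phases, per species.

    Pairs with undefined omega (dS = 0) or, when ``require_significant``,
    a non-significant selection test are dropped; GESD outlier removal is
    applied within each phase before the Mann–Whitney comparison.
    """
    om_a, drop_a = _usable_omegas(pairs_a, alpha, require_significant)
    om_b, drop_b = _usable_omegas(pairs_b, alpha, require_significant)
    reports = []
    for species in sorted(set(om_a) | set(om_b)):
        xs_a = om_a.get(species, [])
        xs_b = om_b.get(species, [])
        if not xs_a or not xs_b:
            logger.warning("species %s: a phase emptied by filtering; skipped", species)
            continue
        n_out_a = n_out_b = 0
        if len(xs_a) >= k_max + 3:
            scan = gesd_outliers(xs_a, alpha=gesd_alpha, k_max=k_max)
            n_out_a = scan.n_outliers
            xs_a = [x for i, x in enumerate(xs_a) if i not in set(scan.outlier_indices)]
        if len(xs_b) >= k_max + 3:
            scan = gesd_outliers(xs_b, alpha=gesd_alpha, k_max=k_max)
            n_out_b = scan.n_outliers
            xs_b = [x for i, x in enumerate(xs_b) if i not in set(scan.outlier_indices)]
        cmp = mann_whitney(xs_a, xs_b, alternative=alternative)
        reports.append(
            PhaseEvolutionReport(
                species=species,
                n_a=len(xs_a),
                n_b=len(xs_b),
                mean_omega_a=cmp.mean_a,
                mean_omega_b=cmp.mean_b,
                median_omega_a=cmp.median_a,
                median_omega_b=cmp.median_b,
                U=cmp.U,
                p_value=cmp.p_value,
                n_outliers_a=n_out_a,
                n_outliers_b=n_out_b,
                dropped_a=drop_a.get(species, 0),
                dropped_b=drop_b.get(species, 0),
            )
        )
    return reports
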