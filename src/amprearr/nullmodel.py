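"""Random-joining microhomology null model and enrichment test.

Under blunt random joining of independent sequences, the seam of a junction
can be extended to the right while the first bases of the retained B flank
match the reference continuation past the A breakend, and to the left
symmetrically.  Each side's extension length is geometric with per-base match
probability ``p = sum_b f_b^2`` (``p = 1/4`` for uniform composition), and the
two sides are independent, so the total two-sided microhomology K has

    P(K = k) = (k + 1) * (1 - p)^2 * p^k

i.e. a negative binomial.  For uniform composition P(K >= 1) = 1 - 9/16 =
0.4375: about 44% of random joins are expected to show microhomology.  The
closed form is validated against exhaustive enumeration of bounded flank
pairs in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

UNIFORM = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


def match_probability(composition: Optional[Dict[str, float]] = None) -> float:
    """Per-base probability that two independent draws agree."""
    comp = UNIFORM if composition is None else composition
    total = sum(comp.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition sums to {total}, expected 1")
    if any(f < 0 for f in comp.values()):
        raise ValueError("composition frequencies must be non-negative")
    return float(sum(f * f for f in comp.values()))


def null_pmf(
    max_k: int, composition: Optional[Dict[str, float]] = None
) -> np.ndarray:
    """Probability mass function of the two-sided microhomology length under
    random joining, for k = 0..max_k; the tail mass P(K > max_k) is lumped
    into the last entry so the pmf sums to 1."""
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    p = match_probability(composition)
    k = np.arange(max_k + 1)
    pmf = (k + 1) * (1.0 - p) ** 2 * p**k
    pmf[-1] = 1.0 - pmf[:-1].sum()
    return pmf


def null_fraction(composition: Optional[Dict[str, float]] = None) -> float:
    """Analytic P(K >= 1): the expected rate of any microhomology if joining
    were random with respect to bp overlap."""
    p = match_probability(composition)
    return 1.0 - (1.0 - p) ** 2


def null_fraction_mc(
    n: int,
    seed: int,
    composition: Optional[Dict[str, float]] = None,
    flank_len: int = 50,
) -> float:
    """Monte-Carlo twin of :func:`null_fraction`.

    Simulates ``n`` random blunt joins on i.i.d. sequence and calls the
    two-sided microhomology with :func:`amprearr.junctions.microhomology_at`,
    returning the fraction with mh >= 1.
    """
    from .model import Breakend, Junction, Orientation
    from .junctions import microhomology_at

    if n < 1:
        raise ValueError("n must be >= 1")
    comp = UNIFORM if composition is None else composition
    match_probability(comp)  # validates
    rng = np.random.default_rng(seed)
    bases = np.array(list(comp.keys()))
    probs = np.array(list(comp.values()))
    hits = 0
    batch = 1000
    done = 0
    while done < n:
        m = min(batch, n - done)
        # each join needs two independent loci: simulate them as two contigs
        draws = rng.choice(bases, size=(m, 2, 2 * flank_len), p=probs)
        for i in range(m):
            genome = {
                "a": "".join(draws[i, 0]),
                "b": "".join(draws[i, 1]),
            }
            j = Junction(
                id="mc",
                arm_a=Breakend("a", flank_len, Orientation.LEFT_RETAINED),
                arm_b=Breakend("b", flank_len + 1, Orientation.RIGHT_RETAINED),
            )
            mh = microhomology_at(j, genome, max_window=flank_len - 1)
            if mh.total >= 1:
                hits += 1
        done += m
    return hits / n


@dataclass
class EnrichmentResult:
    n: int
    n_mh: int
    observed_fraction: float
    null_fraction: float
    p_value: float  # exact one-sided binomial P(X >= observed)
    p_mid: float  # mid-p variant (better calibrated for the discrete test)
    table: "np.ndarray"  # columns: k, observed, expected

    def observed_expected(self) -> Sequence[tuple]:
        return [tuple(row) for row in self.table]


def enrichment_test(
    observed_counts: Sequence[int],
    pmf: Optional[np.ndarray] = None,
    composition: Optional[Dict[str, float]] = None,
) -> EnrichmentResult:
    """One-sided exact binomial test of microhomology enrichment.

    ``observed_counts[k]`` is the number of junctions with two-sided
    microhomology exactly k.  Tests #(mh >= 1) against the null P(mh >= 1)
    under random joining, and tabulates observed vs expected counts per k.
    """
    counts = np.asarray(observed_counts, dtype=int)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no junctions: enrichment test undefined")
    if pmf is None:
        pmf = null_pmf(max(len(counts) - 1, 1), composition)
    if len(pmf) < len(counts):
        raise ValueError("pmf shorter than observed count vector")
    p0 = float(1.0 - pmf[0])
    x = int(counts[1:].sum())
    p_value = float(stats.binom.sf(x - 1, n, p0))
    p_mid = float(stats.binom.sf(x, n, p0) + 0.5 * stats.binom.pmf(x, n, p0))
    expected = np.asarray(pmf[: len(counts)]) * n
    table = np.column_stack([np.arange(len(counts)), counts, expected])
    return EnrichmentResult(
        n=n,
        n_mh=x,
        observed_fraction=x / n,
        null_fraction=p0,
        p_value=p_value,
        p_mid=p_mid,
        table=table,
    )
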