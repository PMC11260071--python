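"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized implementation paths: the coupling
oracle enumerates sequences and residue pairs in pure Python, and the
isotope oracle exhaustively enumerates isotopologues per element with
multinomial weights.
"""

import itertools
import math

import numpy as np

from pksforge.background import GAP_CODE
from pksforge.masscalc import ISOTOPES


def coupling_oracle(codes, w, q, lam):
    """Frobenius-norm SCA coupling matrix by explicit pair counting.

    codes: (N, L) int array (gap = 20); w: (N,) weights; q: (20,) background;
    lam: pseudocount for the phi weights.
    """
    N, L = codes.shape
    C = np.zeros((L, L))

    # gap-excluded single-column frequencies
    f1 = np.zeros((L, 20))
    for i in range(L):
        tot = 0.0
        for s in range(N):
            a = codes[s, i]
            if a != GAP_CODE:
                f1[i, a] += w[s]
                tot += w[s]
        f1[i] /= tot

    phi = np.zeros((L, 20))
    for i in range(L):
        for a in range(20):
            fr = (1 - lam) * f1[i, a] + lam * q[a]
            fr = min(max(fr, 1e-12), 1 - 1e-12)
            phi[i, a] = math.log(fr * (1 - q[a]) / ((1 - fr) * q[a]))

    for i in range(L):
        for j in range(L):
            pair = np.zeros((20, 20))
            tot = 0.0
            for s in range(N):
                a, b = codes[s, i], codes[s, j]
                if a != GAP_CODE and b != GAP_CODE:
                    pair[a, b] += w[s]
                    tot += w[s]
            pair /= tot
            acc = 0.0
            for a in range(20):
                for b in range(20):
                    c = pair[a, b] - f1[i, a] * f1[j, b]
                    term = phi[i, a] * phi[j, b] * c
                    acc += term * term
            C[i, j] = math.sqrt(acc)
    return C


def sequence_weight_oracle(seqs, cutoff):
    """O(N^2) all-pairs identity weighting on raw aligned strings."""
    n = len(seqs)
    w = []
    for i in range(n):
        neighbours = 0
        for j in range(n):
            ident = sum(1 for a, b in zip(seqs[i], seqs[j]) if a == b) / len(seqs[i])
            if ident >= cutoff:
                neighbours += 1
        w.append(1.0 / neighbours)
    return np.array(w)


def isotope_enumeration_oracle(formula, max_shift=10):
    """Exhaustive isotopologue enumeration aggregated by neutron excess.

    Returns dict shift -> (centroid mass, abundance).
    """
    per_element = []
    for el, n in sorted(formula.items()):
        iso = ISOTOPES[el]
        combos = []
        # counts over isotopes of this element summing to n
        for split in _compositions(n, len(iso)):
            ab = math.factorial(n)
            mass = 0.0
            shift = 0
            for k, (m, a, s) in zip(split, iso):
                ab //= math.factorial(k)
                mass += k * m
                shift += k * s
            prob = ab
            for k, (_, a, _) in zip(split, iso):
                prob *= a**k
            combos.append((shift, mass, prob))
        per_element.append(combos)

    agg = {}
    for combo in itertools.product(*per_element):
        shift = sum(c[0] for c in combo)
        if shift > max_shift:
            continue
        mass = sum(c[1] for c in combo)
        prob = math.prod(c[2] for c in combo)
        m_acc, p_acc = agg.get(shift, (0.0, 0.0))
        agg[shift] = (m_acc + mass * prob, p_acc + prob)
    return {
        s: (m / p, p) for s, (m, p) in agg.items() if p > 0
    }


def _compositions(n, k):
    """All k-tuples of nonnegative ints summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)
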