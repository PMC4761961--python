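"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive results from first principles with different
enumeration strategies than the library code (innermost-outward structure
growth, explicit pair tables, scipy root-finding for mass balance), so that
agreement is evidence and not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def brute_force_inverted_repeat(seq, min_arm=5, min_loop=3, allow_wobble=False):
    """All-splits enumeration of terminal-arm inverted repeats.

    Returns (arm, n_wc, n_wobble, n_mismatches) of the best register, or None
    under the same contract as the library detector.
    """
    s = seq.upper().replace("T", "U")
    L = len(s)
    candidates = []
    for loop in range(min_loop, L + 1):
        if (L - loop) % 2:
            continue
        arm = (L - loop) // 2
        if arm < 1:
            continue
        n_wc = n_wob = 0
        for i in range(arm):
            a, b = s[i], s[L - 1 - i]
            if _COMP[a] == b:
                n_wc += 1
            elif (a, b) in _WOBBLE:
                n_wob += 1
        score = n_wc + (n_wob if allow_wobble else 0)
        candidates.append((score, arm, n_wc, n_wob, arm - n_wc - n_wob))
    if not candidates:
        return None
    max_possible_arm = max(c[1] for c in candidates)
    best = max(candidates, key=lambda c: (c[0], c[1]))
    if max_possible_arm < min_arm or best[0] == 0:
        return None
    return best[1], best[2], best[3], best[4]


def brute_force_hairpin_dg(seq, table, min_loop=3):
    """Minimum dG over every legal single-stem structure, grown inside-out.

    Enumerates each possible *innermost* pair, then every outward contiguous
    extension, scoring with direct table lookups.  Returns 0.0 when no
    structure is stabilizing (open chain).
    """
    s = seq.upper().replace("T", "U")
    L = len(s)
    weak = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
    best = 0.0
    for p in range(L):
        for q in range(p + min_loop + 1, L):
            if (s[p], s[q]) not in _CANONICAL:
                continue
            # stems whose innermost pair is (p, q): extend outward
            pairs = [(p, q)]
            while True:
                loop_len = pairs[0][1] - pairs[0][0] - 1  # innermost enclosure
                outer = pairs[-1]
                dg = table.loop_initiation(loop_len)
                for k in range(len(pairs) - 1):
                    inner_i, inner_j = pairs[k]
                    outer_i, outer_j = pairs[k + 1]
                    dg += table.stack(s[outer_i] + s[outer_j], s[inner_i] + s[inner_j])
                if (s[outer[0]], s[outer[1]]) in weak:
                    dg += table.terminal_au_penalty
                best = min(best, dg)
                ii, jj = outer[0] - 1, outer[1] + 1
                if ii < 0 or jj >= L or (s[ii], s[jj]) not in _CANONICAL:
                    break
                pairs.append((ii, jj))
    return best


def mass_balance_bound(site_tot, x_tot, ka):
    """Bound-complex concentration by direct root finding on the mass balance
    Ka = C / ((S - C) (X - C)), independent of the closed-form quadratic."""
    out = []
    for S, X in zip(np.atleast_1d(site_tot), np.atleast_1d(x_tot)):
        if S <= 0 or X <= 0:
            out.append(0.0)
            continue
        f = lambda c: ka * (S - c) * (X - c) - c
        out.append(brentq(f, 0.0, min(S, X) * (1 - 1e-15), xtol=1e-24, rtol=1e-15))
    return np.array(out)


def studentized_min_gamma_mc(shape, n_modes, n_rep, rng):
    """Monte-Carlo expectation of the studentized minimum of gamma samples."""
    x = rng.gamma(shape, 1.0, size=(n_rep, n_modes))
    z = (x.min(axis=1) - x.mean(axis=1)) / x.std(axis=1, ddof=1)
    return float(z.mean()), float(z.std(ddof=1) / np.sqrt(n_rep))
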