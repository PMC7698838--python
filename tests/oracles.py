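"""Independent reference implementations used as oracles by the test suite.

These deliberately re-derive behaviour with different code paths (string
patterns, exhaustive enumeration) so they stay independent of the package
implementations they check.
"""

import itertools

import numpy as np

from somnofuse.stages import N1, N2, N3, REM, W

RULE_STRINGS = [
    ("W REM N2", "W N1 N2"),
    ("N1 REM N2", "N1 N1 N2"),
    ("N2 X N2", "N2 N2 N2"),
    ("REM X REM", "REM REM REM"),
]
NAME2CODE = {"W": W, "N1": N1, "N2": N2, "N3": N3, "REM": REM}


def naive_rule_rewrite(hyp):
    """String-pattern oracle: positional pre-N2 REM rule, then each triple
    rule as a left-to-right stride-1 in-place pass."""
    out = list(hyp)
    first_n2 = next((i for i, s in enumerate(out) if s == N2), 0)
    for i in range(first_n2):
        if out[i] == REM:
            out[i] = N1
    for match, repl in RULE_STRINGS:
        m = match.split()
        r = [NAME2CODE[t] for t in repl.split()]
        for t in range(len(out) - 2):
            window = out[t : t + 3]
            ok = all(tok == "X" or NAME2CODE[tok] == w for tok, w in zip(m, window))
            if ok:
                out[t : t + 3] = r if "X" not in m else [window[0], r[1], window[2]]
    return np.array(out)


def brute_force_viterbi(observed, params):
    """Enumerate all 5^L hidden paths; return (optimal_paths, best_logprob)."""
    with np.errstate(divide="ignore"):
        logA, logB, logpi = np.log(params.A), np.log(params.B), np.log(params.pi)
    scored = []
    for path in itertools.product(range(5), repeat=len(observed)):
        lp = logpi[path[0]] + logB[path[0], observed[0]]
        for t in range(1, len(observed)):
            lp += logA[path[t - 1], path[t]] + logB[path[t], observed[t]]
        scored.append((lp, path))
    best_lp = max(lp for lp, _ in scored)
    optimal = [path for lp, path in scored if lp >= best_lp - 1e-9]
    return optimal, best_lp


def path_logprob(path, observed, params):
    with np.errstate(divide="ignore"):
        logA, logB, logpi = np.log(params.A), np.log(params.B), np.log(params.pi)
    lp = logpi[path[0]] + logB[path[0], observed[0]]
    for t in range(1, len(observed)):
        lp += logA[path[t - 1], path[t]] + logB[path[t], observed[t]]
    return lp
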