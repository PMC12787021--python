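"""Independent brute-force oracles used by several test modules.

These deliberately avoid the implementation's code paths (no pruning, no
ordering shortcuts) so they can serve as ground truth for equivalence
tests.
"""

import itertools

from qnmr1d.profilematch import multiplet_lines


def brute_force_best(peaks, pattern, freq):
    """Exhaustively enumerate every injective assignment of all the
    pattern's expected lines (across all sub-signals jointly) to peaks and
    return (best_score, best_index_tuple), or (None, None) if no valid
    assignment exists.

    Scoring mirrors the documented rule -- sum(|d_delta|/tol) +
    sum(|d_J|/J_tol) with all lines within delta tolerance and measured
    couplings within J tolerance -- but is computed by raw enumeration
    over permutations of the full peak list.
    """
    subs = pattern.sub_signals
    lines_per_sub = [sorted(multiplet_lines(s, freq)) for s in subs]
    n_lines = sum(len(ls) for ls in lines_per_sub)
    best_score, best_idx = None, None
    indices = range(len(peaks))
    for perm in itertools.permutations(indices, n_lines):
        pos = 0
        score = 0.0
        ok = True
        for sub, lines in zip(subs, lines_per_sub):
            chosen = perm[pos:pos + len(lines)]
            pos += len(lines)
            centers = [peaks[i].center_ppm for i in chosen]
            if any(centers[k] >= centers[k + 1]
                   for k in range(len(centers) - 1)):
                ok = False
                break
            for c, (ppm_e, _) in zip(centers, lines):
                if abs(c - ppm_e) > pattern.delta_tol_ppm:
                    ok = False
                    break
                score += abs(c - ppm_e) / pattern.delta_tol_ppm
            if not ok:
                break
            score += _j_penalty(sub, centers, freq, pattern.j_tol_hz)
            if score == float("inf"):
                ok = False
                break
        if not ok:
            continue
        if best_score is None or score < best_score:
            best_score, best_idx = score, perm
    return best_score, best_idx


def _j_penalty(sub, centers, freq, j_tol):
    devs = []
    if sub.multiplicity == "d":
        devs = [abs((centers[1] - centers[0]) * freq - sub.j_hz[0])]
    elif sub.multiplicity == "q":
        sp = [(centers[i + 1] - centers[i]) * freq for i in range(3)]
        devs = [abs(sum(sp) / 3.0 - sub.j_hz[0])]
    elif sub.multiplicity == "dd":
        j_big, j_small = sorted(sub.j_hz, reverse=True)
        small = ((centers[1] - centers[0]) + (centers[3] - centers[2])) / 2 * freq
        big = ((centers[2] + centers[3]) - (centers[0] + centers[1])) / 2 * freq
        devs = [abs(small - j_small), abs(big - j_big)]
    if any(d > j_tol for d in devs):
        return float("inf")
    return sum(d / j_tol for d in devs)
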