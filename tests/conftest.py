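"""Shared fixtures and independent oracles used across the test suite."""

import numpy as np
import pytest

from strandpair import PairingLabels, PairingProbMap, SimulationParams
from strandpair.features import separation_mask


def make_dssp_text(n_residues, ss_letters, bp1, bp2, break_after=None):
    """Build a synthetic classic-format DSSP residue table.

    Column layout follows the classic dssp program output: residue number
    in [0:5], amino acid at 13, structure letter at 16, BP1 in [25:29] and
    BP2 in [29:33].  ``bp1``/``bp2`` are 1-based DSSP residue numbers
    (0 = no partner).  ``break_after`` optionally inserts a '!' chain-break
    row after the given 1-based residue.
    """
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N",
    ]
    num = 0
    for k in range(n_residues):
        num += 1
        lines.append(f"{num:5d}{num:5d} A {'ACDEFGHIKLMN'[k % 12]}  "
                     f"{ss_letters[k]}{'':8}{bp1[k]:4d}{bp2[k]:4d}")
        if break_after is not None and k + 1 == break_after:
            num += 1
            lines.append(f"{num:5d}{'':8}!{'':11}{0:4d}{0:4d}")
    return "\n".join(lines) + "\n"


def hairpin_dssp_text():
    """Two antiparallel strands of a 12-residue hairpin.

    Strand residues are DSSP numbers 3-6 and 9-12 with bridge partners
    3<->12, 4<->11, 5<->10, 6<->9; hand-read expected pairs (0-based) are
    {(2, 11), (3, 10), (4, 9), (5, 8)}.
    """
    ss = list("  EEEE  EEEE")
    bp1 = [0, 0, 12, 11, 10, 9, 0, 0, 6, 5, 4, 3]
    bp2 = [0] * 12
    return make_dssp_text(12, ss, bp1, bp2)


def dense_gaussian_oracle(values, t):
    """Dense (non-separable) Gaussian smoothing oracle with symmetric
    boundary handling, for cross-checking the separable implementation."""
    sigma = np.sqrt(t)
    radius = max(1, int(np.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-(x ** 2) / (2.0 * t))
    k1 /= k1.sum()
    k2 = np.outer(k1, k1)
    padded = np.pad(values, radius, mode="symmetric")
    out = np.empty_like(values, dtype=float)
    n = values.shape[0]
    m = values.shape[1]
    for i in range(n):
        for j in range(m):
            out[i, j] = np.sum(padded[i:i + 2 * radius + 1, j:j + 2 * radius + 1] * k2)
    return out


def hessian_oracle(f):
    """Per-pixel Hessian eigenpairs via numpy.linalg.eigh, using the same
    finite-difference stencils as the contract (central interior, shifted
    at borders for second derivatives; numpy.gradient for the cross term)."""
    n, m = f.shape

    def second(fa, axis):
        g = np.moveaxis(fa, axis, 0)
        d = np.empty_like(g)
        d[1:-1] = g[2:] - 2 * g[1:-1] + g[:-2]
        d[0] = g[0] - 2 * g[1] + g[2]
        d[-1] = g[-1] - 2 * g[-2] + g[-3]
        return np.moveaxis(d, 0, axis)

    lii = second(f, 0)
    ljj = second(f, 1)
    lij = np.gradient(np.gradient(f, axis=0), axis=1)
    lam1 = np.empty_like(f)
    lam2 = np.empty_like(f)
    theta = np.empty_like(f)
    for i in range(n):
        for j in range(m):
            h = np.array([[lii[i, j], lij[i, j]], [lij[i, j], ljj[i, j]]])
            w, v = np.linalg.eigh(h)
            lam1[i, j], lam2[i, j] = w
            theta[i, j] = np.mod(np.arctan2(v[1, 0], v[0, 0]), np.pi)
    return lam1, lam2, theta


def ridge_features_oracle(values, scales, gamma):
    """Brute-force full-pipeline ridge features (height channel only needs
    eigenvalues, so orientation conventions cannot diverge)."""
    best = np.zeros_like(values, dtype=float)
    best_theta = np.zeros_like(values, dtype=float)
    for t in scales:
        lam1, _, theta = hessian_oracle(dense_gaussian_oracle(values, t))
        s = (t ** gamma) * np.maximum(0.0, -lam1)
        take = s > best
        best_theta = np.where(take, theta, best_theta)
        best = np.where(take, s, best)
    return best, best_theta


def prob_map_from_scores(length, scored_pairs):
    """Build a PairingProbMap with given {(i, j): score} entries."""
    p = np.zeros((length, length))
    for (i, j), s in scored_pairs.items():
        p[i, j] = p[j, i] = s
    return PairingProbMap(p)


def raw_map_baseline_f1(proteins):
    """F1 of thresholding the better raw simulated contact map at its own
    pooled F1-optimal cutoff — the no-learning reference."""
    from strandpair.evaluation import _best_f1_over_cutoffs, _pool_scores

    best = 0.0
    for pick in (lambda p: p.map_a, lambda p: p.map_b):
        pool = []
        for p in proteins:
            m = np.clip(pick(p).values, 0.0, 1.0)
            m = np.where(separation_mask(p.labels.length), m, 0.0)
            pool.append((PairingProbMap(m), p.labels))
        scores, y = _pool_scores(pool)
        f1, _ = _best_f1_over_cutoffs(scores, y)
        best = max(best, f1)
    return best


@pytest.fixture
def noiseless_params():
    return SimulationParams(length_range=(40, 70), n_strand_range=(2, 4),
                            fp_density=0.0, miss_rate=0.0, blur_sigma=0.0,
                            ss_error_rate=0.0, ss_jitter=0.0)
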