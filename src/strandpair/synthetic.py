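"""Synthetic beta-sheet proteins: planted topologies, ground-truth pairing
labels, noisy contact maps and secondary-structure profiles.

The generator emulates the signal the predictor exploits: a pair of
parallel strands leaves a diagonal line of high contact values on the map,
an antiparallel pair an anti-diagonal line, sitting on a near-diagonal
sequence-neighbor band, with false positives, missed contacts and blur as
noise.  Two independently corrupted maps per protein stand in for the two
upstream contact predictors.  In the noiseless limit the simulation is
exactly invertible: thresholding the map recovers the planted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import CANONICAL_AA, MIN_SEPARATION, ContactMap, PairingLabels, SequenceProfile
from .ridge import RidgeParams, compute_ridge_features

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"

_MIN_STRAND, _MAX_STRAND = 3, 10
_MIN_LOOP = 2           # residues between consecutive strands
_MIN_OVERLAP = 3        # aligned residues per strand pairing


@dataclass
class SheetTopology:
    """Planted strands and their pairings.

    strands: list of (start, length); pairings: list of
    (strand_a, strand_b, orientation, register_offset).  Pairings form
    chains, so each strand has at most two partners (edge strands one,
    interior strands two), as in a real sheet.
    """

    length: int
    strands: list = field(default_factory=list)
    pairings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -_MIN_LOOP - 1
        for start, slen in self.strands:
            if not (_MIN_STRAND <= slen <= _MAX_STRAND):
                raise ValueError(f"strand length {slen} outside [{_MIN_STRAND}, {_MAX_STRAND}]")
            if start - (prev_end + 1) < _MIN_LOOP:
                raise ValueError("strands overlap or are separated by < 2 loop residues")
            if start + slen > self.length:
                raise ValueError("strand extends past the chain end")
            prev_end = start + slen - 1
        for a, b, orient, reg in self.pairings:
            if a == b:
                raise ValueError("a strand cannot pair with itself")
            if orient not in (PARALLEL, ANTIPARALLEL):
                raise ValueError(f"unknown orientation {orient!r}")
            if not _aligned_span(self.strands[a], self.strands[b], orient, reg):
                raise ValueError("pairing's aligned segment does not fit both strands")


def _aligned_span(strand_a, strand_b, orientation, register):
    """Residue pairs produced by one pairing, or None if the overlap is < 3.

    For a parallel pairing with register r, residue sa+m pairs with
    sb+r+m; for antiparallel, sa+m pairs with sb+(lb-1)-r-m.  Only offsets
    keeping at least _MIN_OVERLAP aligned residues are valid.
    """
    sa, la = strand_a
    sb, lb = strand_b
    pairs = []
    for m in range(la):
        n = register + m if orientation == PARALLEL else (lb - 1) - register - m
        if 0 <= n < lb:
            pairs.append((sa + m, sb + n))
    if len(pairs) < _MIN_OVERLAP:
        return None
    return pairs


@dataclass
class SimulationParams:
    """Noise model and size ranges for the generator.

    Defaults are the desk-scale regime: chains of 50-120 residues with 2-6
    strands, false-positive density 0.01, miss rate 0.1, blur sigma 0.5
    and secondary-structure error rate 0.1.
    """

    length_range: tuple = (50, 120)
    n_strand_range: tuple = (2, 6)
    fp_density: float = 0.01
    miss_rate: float = 0.1
    blur_sigma: float = 0.5
    ss_error_rate: float = 0.1
    ss_jitter: float = 50.0     # Dirichlet concentration; 0 disables jitter
    n_homologs_range: tuple = (10.0, 10000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("length_range", "n_strand_range", "n_homologs_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not ordered")
        for name in ("fp_density", "miss_rate", "ss_error_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be nonnegative")


def sample_topology(params: SimulationParams, rng: np.random.Generator) -> SheetTopology:
    """Draw a random valid topology: placed strands plus a pairing chain.

    Strand lengths are 3-10 residues with >= 2 loop residues between
    strands; pairings link the strands into a chain in random order, with
    uniform orientations and register offsets drawn uniformly from those
    keeping >= 3 aligned residues.
    """
    for _attempt in range(200):
        length = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
        n_strands = int(rng.integers(params.n_strand_range[0], params.n_strand_range[1] + 1))
        if n_strands == 0:
            return SheetTopology(length=length)
        lengths = rng.integers(_MIN_STRAND, _MAX_STRAND + 1, size=n_strands)
        slack = length - int(lengths.sum()) - _MIN_LOOP * (n_strands - 1)
        if slack < 0:
            continue
        # distribute the slack into n_strands + 1 gaps (before, between, after)
        cuts = np.sort(rng.integers(0, slack + 1, size=n_strands))
        extra = np.diff(np.concatenate([[0], cuts]))
        strands = []
        pos = 0
        for k in range(n_strands):
            pos += int(extra[k]) + (_MIN_LOOP if k > 0 else 0)
            strands.append((pos, int(lengths[k])))
            pos += int(lengths[k])
        order = rng.permutation(n_strands)
        pairings = []
        ok = True
        for a, b in zip(order[:-1], order[1:]):
            a, b = int(a), int(b)
            orient = PARALLEL if rng.random() < 0.5 else ANTIPARALLEL
            la, lb = strands[a][1], strands[b][1]
            feasible = [r for r in range(-(la - _MIN_OVERLAP), lb - _MIN_OVERLAP + 1)
                        if _aligned_span(strands[a], strands[b], orient, r)]
            if not feasible:
                ok = False
                break
            pairings.append((a, b, orient, int(rng.choice(feasible))))
        if not ok:
            continue
        return SheetTopology(length=length, strands=strands, pairings=pairings)
    raise ValueError("could not sample a feasible topology; widen the parameter ranges")


def topology_to_labels(topo: SheetTopology) -> PairingLabels:
    """Ground-truth hydrogen-bonded pairs implied by the planted pairings.

    Parallel pairings contribute (a+m, b+m) along the aligned segment,
    antiparallel ones (a+m, b+k-1-m); pairs closer than the minimum
    sequence separation are dropped.
    """
    pairs = set()
    for a, b, orient, reg in topo.pairings:
        for i, j in _aligned_span(topo.strands[a], topo.strands[b], orient, reg) or []:
            if abs(i - j) >= MIN_SEPARATION:
                pairs.add((min(i, j), max(i, j)))
    return PairingLabels(length=topo.length, pairs=frozenset(pairs))


def simulate_contact_map(labels: PairingLabels, length: int,
                         params: SimulationParams, rng: np.random.Generator,
                         source_tag: str = "synthetic") -> ContactMap:
    """Corrupt the ideal contact map of a label set.

    Base map: 1 at label pairs and on the sequence-neighbor band
    |i - j| <= 2.  Each true pair is zeroed with probability miss_rate,
    the map is Gaussian-blurred with blur_sigma, each cell still exactly
    zero becomes uniform(0.3, 1) with probability fp_density, and the
    result is clipped to [0, 1] and symmetrized.
    """
    m = np.zeros((length, length))
    idx = np.arange(length)
    m[np.abs(np.subtract.outer(idx, idx)) <= 2] = 1.0
    for i, j in sorted(labels.pairs):
        if rng.random() < params.miss_rate:
            continue
        m[i, j] = m[j, i] = 1.0
    if params.blur_sigma > 0:
        m = gaussian_filter(m, params.blur_sigma, mode="constant")
    iu, ju = np.triu_indices(length, k=1)
    zero = m[iu, ju] == 0.0
    hits = zero & (rng.random(len(iu)) < params.fp_density)
    values = rng.uniform(0.3, 1.0, size=int(hits.sum()))
    m[iu[hits], ju[hits]] = values
    m[ju[hits], iu[hits]] = values
    return ContactMap(np.clip(m, 0.0, 1.0), source_tag=source_tag)


def simulate_profile(topo: SheetTopology, params: SimulationParams,
                     rng: np.random.Generator) -> SequenceProfile:
    """Emulated secondary-structure profile and sequence for a topology.

    Strand residues get ss3 base (0.05, 0.9, 0.05), all others
    (0.1, 0.05, 0.85); with probability ss_error_rate the strand/coil
    assignment flips before Dirichlet jitter is applied.  Sequence letters
    are uniform over the 20 canonical residues and the homolog count is
    log-uniform over n_homologs_range.
    """
    in_strand = np.zeros(topo.length, dtype=bool)
    for start, slen in topo.strands:
        in_strand[start:start + slen] = True
    strand_base = np.array([0.05, 0.9, 0.05])
    coil_base = np.array([0.1, 0.05, 0.85])
    rows = np.empty((topo.length, 3))
    for i in range(topo.length):
        is_strand = in_strand[i]
        if rng.random() < params.ss_error_rate:
            is_strand = not is_strand
        base = strand_base if is_strand else coil_base
        if params.ss_jitter > 0:
            rows[i] = rng.dirichlet(base * params.ss_jitter)
        else:
            rows[i] = base
    seq = "".join(rng.choice(list(CANONICAL_AA)) for _ in range(topo.length))
    lo, hi = params.n_homologs_range
    n_hom = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return SequenceProfile(sequence=seq, ss3=rows, n_homologs=n_hom)


@dataclass
class SyntheticProtein:
    """One generated example: two noisy maps, their ridge features, the
    profile and the ground-truth labels."""

    protein_id: str
    topology: SheetTopology
    map_a: ContactMap
    map_b: ContactMap
    ridge_a: object
    ridge_b: object
    profile: SequenceProfile
    labels: PairingLabels


def generate_dataset(n: int, params: SimulationParams | None = None,
                     seed: int | None = None,
                     ridge_params: RidgeParams | None = None) -> list:
    """Generate n independent synthetic proteins, deterministically per seed.

    The two contact maps of each protein are two independently corrupted
    copies of the same ground truth, emulating two upstream predictors
    with uncorrelated errors.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    params = params or SimulationParams()
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    ridge_params = ridge_params or RidgeParams()
    out = []
    for k in range(n):
        topo = sample_topology(params, rng)
        labels = topology_to_labels(topo)
        map_a = simulate_contact_map(labels, topo.length, params, rng, "synthetic_a")
        map_b = simulate_contact_map(labels, topo.length, params, rng, "synthetic_b")
        profile = simulate_profile(topo, params, rng)
        out.append(SyntheticProtein(
            protein_id=f"p{k:04d}",
            topology=topo,
            map_a=map_a, map_b=map_b,
            ridge_a=compute_ridge_features(map_a, ridge_params),
            ridge_b=compute_ridge_features(map_b, ridge_params),
            profile=profile,
            labels=labels))
    return out
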