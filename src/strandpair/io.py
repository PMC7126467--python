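"""Readers and writers for every on-disk format the pipeline touches.

Internal residue indices are 0-based everywhere; formats that are 1-based
(CASP RR lists, DSSP residue numbers) are converted at this boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 canonical amino-acid one-letter codes, in one-hot channel order
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: minimum sequence separation for a cross-strand partner: the tightest
#: beta hairpin bridges residue i with i+3, so closer pairs are impossible
MIN_SEPARATION = 3


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


def _as_square(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{what} must be a square matrix, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what} contains non-finite entries")
    return values


@dataclass
class ContactMap:
    """Symmetric L x L map of predicted residue-residue contact strength.

    Contacts are conventionally defined by a C-beta/C-beta distance below
    8 angstrom; the map holds each upstream predictor's score for that event.
    Asymmetric inputs are symmetrized by averaging with the transpose.
    """

    values: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        v = _as_square(self.values, "contact map")
        self.values = (v + v.T) / 2.0
        if self.length < 1:
            raise ValueError("contact map must cover at least one residue")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class SequenceProfile:
    """Per-residue sequence information: letters, 3-state secondary-structure
    probabilities (helix, strand, coil) and the scalar homolog count N."""

    sequence: str
    ss3: np.ndarray
    n_homologs: float = 0.0

    def __post_init__(self) -> None:
        self.ss3 = np.asarray(self.ss3, dtype=float)
        if self.ss3.ndim != 2 or self.ss3.shape[1] != 3:
            raise ValueError(f"ss3 must be L x 3, got shape {self.ss3.shape}")
        if len(self.sequence) != self.ss3.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != ss3 rows {self.ss3.shape[0]}"
            )
        sums = self.ss3.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"ss3 row {bad} sums to {sums[bad]:.4f}, not 1")
        if self.n_homologs < 0:
            raise ValueError("homolog count must be nonnegative")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PairingLabels:
    """Ground-truth set of hydrogen-bonded cross-strand residue pairs.

    Pairs are unordered, 0-based, and must be at least MIN_SEPARATION apart."""

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        canon = set()
        for i, j in self.pairs:
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            if i < 0 or j >= self.length:
                raise ValueError(f"pair ({i}, {j}) out of range for L={self.length}")
            if j - i < MIN_SEPARATION:
                raise ValueError(f"pair ({i}, {j}) closer than minimum separation {MIN_SEPARATION}")
            canon.add((i, j))
        self.pairs = frozenset(canon)

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix."""
        y = np.zeros((self.length, self.length))
        for i, j in self.pairs:
            y[i, j] = y[j, i] = 1.0
        return y


@dataclass
class PairingProbMap:
    """Symmetric L x L matrix of beta-beta hydrogen-bond pairing probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = _as_square(self.probs, "probability map")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        if np.max(np.abs(p - p.T)) > 1e-6:
            raise ValueError("probability map is not symmetric")
        p = np.clip((p + p.T) / 2.0, 0.0, 1.0)
        sep = np.abs(np.subtract.outer(np.arange(p.shape[0]), np.arange(p.shape[0])))
        p[sep < MIN_SEPARATION] = 0.0
        self.probs = p

    @property
    def length(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(path, dialect: str = "matrix", length_hint: int | None = None,
                        source_tag: str | None = None) -> ContactMap:
    """Read a contact map from a dense whitespace matrix or a CASP RR list.

    The matrix dialect is L whitespace-separated rows of L numbers (CCMpred
    output).  The RR dialect is "i j dmin dmax prob" with 1-based indices;
    ``length_hint`` is then required and unlisted cells default to 0.
    The returned map is symmetrized as (M + M^T) / 2.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    tag = source_tag if source_tag is not None else dialect
    if dialect == "matrix":
        rows = []
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric token ({exc})") from None
            rows.append((lineno, row))
        if not rows:
            raise FormatError(f"{path}: empty matrix file")
        width = len(rows[0][1])
        for lineno, row in rows:
            if len(row) != width:
                raise FormatError(
                    f"{path}: line {lineno}: ragged row of {len(row)} values, expected {width}")
        if len(rows) != width:
            raise FormatError(f"{path}: {len(rows)} rows but {width} columns; matrix must be square")
        return ContactMap(np.array([r for _, r in rows]), source_tag=tag)
    if dialect == "rr":
        if length_hint is None:
            raise ValueError("length_hint is required for the rr dialect")
        m = np.zeros((length_hint, length_hint))
        seen_data = False
        for lineno, line in enumerate(lines, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#"):
                continue
            try:
                i, j = int(toks[0]), int(toks[1])
                prob = float(toks[4]) if len(toks) >= 5 else float(toks[2])
            except (ValueError, IndexError):
                if not seen_data:
                    continue  # header line (PFRMAT RR, TARGET, sequence, ...)
                raise FormatError(f"{path}: line {lineno}: malformed RR record {line!r}") from None
            seen_data = True
            if not (1 <= i <= length_hint and 1 <= j <= length_hint):
                raise FormatError(
                    f"{path}: line {lineno}: index ({i}, {j}) out of [1, {length_hint}]")
            m[i - 1, j - 1] = m[j - 1, i - 1] = prob
        return ContactMap(m, source_tag=tag)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# sequence + secondary-structure profiles
# ---------------------------------------------------------------------------

def read_sequence_profile(fasta_path, ss3_path, n_homologs: float = 0.0) -> SequenceProfile:
    """Read a single-record FASTA plus a 3-state secondary-structure profile.

    The ss3 file holds one row per residue whose last three numeric columns
    are the (helix, strand, coil) probabilities; '#' comment lines are
    ignored.  Rows are renormalized when their sum is within 1e-2 of 1.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{fasta_path}: expected exactly one FASTA record, found {len(records)}")
    sequence = str(records[0].seq).upper()
    rows = []
    with open(ss3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise FormatError(f"{ss3_path}: line {lineno}: fewer than 3 columns")
            try:
                probs = [float(t) for t in toks[-3:]]
            except ValueError:
                raise FormatError(f"{ss3_path}: line {lineno}: non-numeric probability") from None
            s = sum(probs)
            if abs(s - 1.0) > 1e-2:
                raise FormatError(
                    f"{ss3_path}: line {lineno}: probabilities sum to {s:.4f}, not 1")
            rows.append([p / s for p in probs])
    if len(rows) != len(sequence):
        raise FormatError(
            f"length mismatch: FASTA {fasta_path} has {len(sequence)} residues "
            f"but {ss3_path} has {len(rows)} rows")
    return SequenceProfile(sequence=sequence, ss3=np.array(rows), n_homologs=n_homologs)


# ---------------------------------------------------------------------------
# DSSP ground truth
# ---------------------------------------------------------------------------

def parse_dssp_bridge_partners(dssp_text: str) -> PairingLabels:
    """Extract beta-beta bridge partners from classic DSSP output text.

    For each residue whose structure letter is E or B, the BP1/BP2 columns
    name its bridge partner(s) by DSSP residue number.  Fixed column
    positions of the classic format are used (the table is column-aligned
    and token splitting breaks on crowded fields): structure letter at
    column 16, BP1 at 25:29, BP2 at 29:33.  Chain-break rows ('!') are
    skipped; self-pairings are rejected with a warning.
    """
    lines = dssp_text.splitlines()
    start = None
    for k, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            start = k + 1
            break
    if start is None:
        raise FormatError("DSSP text has no residue table header ('#  RESIDUE AA ...')")

    # DSSP numbers residues sequentially including chain-break rows; map the
    # DSSP number of each real residue to its 0-based position in the chain.
    dssp_to_seq: dict[int, int] = {}
    seq_pos = 0
    table = []
    for line in lines[start:]:
        if len(line) < 17 or not line[:5].strip():
            continue
        try:
            num = int(line[:5])
        except ValueError:
            continue
        if line[13] == "!":
            continue
        dssp_to_seq[num] = seq_pos
        table.append((num, line))
        seq_pos += 1

    pairs = set()
    for num, line in table:
        ss = line[16]
        if ss not in ("E", "B"):
            continue
        for lo, hi in ((25, 29), (29, 33)):
            fldstr = line[lo:hi].strip() if len(line) >= hi else ""
            if not fldstr:
                continue
            try:
                partner = int(fldstr)
            except ValueError:
                continue
            if partner == 0:
                continue
            if partner == num:
                warnings.warn(f"DSSP residue {num} lists itself as bridge partner; skipped")
                continue
            if partner not in dssp_to_seq:
                continue
            i, j = dssp_to_seq[num], dssp_to_seq[partner]
            if abs(i - j) < MIN_SEPARATION:
                continue
            pairs.add((min(i, j), max(i, j)))
    return PairingLabels(length=seq_pos, pairs=frozenset(pairs))


# ---------------------------------------------------------------------------
# probability matrices and pair lists
# ---------------------------------------------------------------------------

def write_probability_matrix(pmap: PairingProbMap, path) -> None:
    """Write an L x L probability matrix as plain text with 6 decimals."""
    np.savetxt(path, pmap.probs, fmt="%.6f")


def read_probability_matrix(path) -> PairingProbMap:
    """Read a plain-text probability matrix; validates symmetry and range."""
    try:
        values = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    try:
        return PairingProbMap(values)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_pair_list(labels: PairingLabels, path) -> None:
    """Write pairing labels as an RR-style list of 1-based "i j" lines."""
    with open(path, "w") as fh:
        fh.write(f"# L={labels.length} beta-beta pairs (1-based)\n")
        for i, j in sorted(labels.pairs):
            fh.write(f"{i + 1} {j + 1}\n")


def read_pair_list(path) -> PairingLabels:
    """Read labels written by :func:`write_pair_list`."""
    length = None
    pairs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                if "L=" in line:
                    length = int(line.split("L=")[1].split()[0])
                continue
            if not line:
                continue
            toks = line.split()
            try:
                i, j = int(toks[0]) - 1, int(toks[1]) - 1
            except (ValueError, IndexError):
                raise FormatError(f"{path}: line {lineno}: malformed pair {line!r}") from None
            pairs.add((min(i, j), max(i, j)))
    if length is None:
        length = max((j for _, j in pairs), default=0) + 1
    return PairingLabels(length=length, pairs=frozenset(pairs))
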