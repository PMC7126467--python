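"""Distance-constraint export for contact-guided folding.

Predicted beta-beta pairs are high-confidence and get a tight 3.5-6 A
C-beta range; the set is then enriched to one constraint per residue (1 L)
with the highest-ranked non-redundant pairs from a general contact map,
which get the looser 3.5-10 A range, following the contact-guided folding
protocol the predictions feed into.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io import MIN_SEPARATION, ContactMap, FormatError, PairingProbMap

BETA_RANGE = (3.5, 6.0)
GENERAL_RANGE = (3.5, 10.0)


class Constraint(NamedTuple):
    i: int
    j: int
    dmin: float
    dmax: float
    confidence: float
    tag: str


@dataclass
class ConstraintSet:
    """Ordered distance constraints, beta entries first, at most L total."""

    length: int
    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        if len(self.entries) > self.length:
            raise ValueError("constraint count exceeds the protein length")
        for e in self.entries:
            key = (min(e.i, e.j), max(e.i, e.j))
            if key in seen:
                raise ValueError(f"duplicate constraint for pair {key}")
            seen.add(key)
            if abs(e.i - e.j) < MIN_SEPARATION:
                raise ValueError(f"pair {key} closer than minimum separation")
            expected = BETA_RANGE if e.tag == "beta" else GENERAL_RANGE
            if (e.dmin, e.dmax) != expected:
                raise ValueError(f"{e.tag} entry has range ({e.dmin}, {e.dmax})")


def build_constraints(beta: PairingProbMap, general: ContactMap,
                      cutoff: float) -> ConstraintSet:
    """Beta pairs above cutoff (top-L by probability), topped up with the
    highest-ranked non-redundant general-map pairs until min(L, available).

    Ordering is deterministic: descending score, ties broken by smaller i
    then smaller j.
    """
    if beta.length != general.length:
        raise ValueError(
            f"length mismatch: probabilities L={beta.length}, general map L={general.length}")
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    length = beta.length
    iu, ju = np.triu_indices(length, k=MIN_SEPARATION)

    bscore = beta.probs[iu, ju]
    border = sorted(np.nonzero(bscore >= cutoff)[0],
                    key=lambda k: (-bscore[k], iu[k], ju[k]))
    entries = [Constraint(int(iu[k]), int(ju[k]), *BETA_RANGE, float(bscore[k]), "beta")
               for k in border[:length]]
    taken = {(e.i, e.j) for e in entries}

    gscore = general.values[iu, ju]
    gorder = sorted(np.nonzero(gscore > 0)[0],
                    key=lambda k: (-gscore[k], iu[k], ju[k]))
    for k in gorder:
        if len(entries) >= length:
            break
        pair = (int(iu[k]), int(ju[k]))
        if pair in taken:
            continue
        entries.append(Constraint(*pair, *GENERAL_RANGE,
                                  float(np.clip(gscore[k], 0.0, 1.0)), "general"))
        taken.add(pair)
    return ConstraintSet(length=length, entries=entries)


def write_rr_constraints(cs: ConstraintSet, path) -> None:
    """Write "i j dmin dmax confidence" lines with 1-based indices."""
    with open(path, "w") as fh:
        fh.write(f"# L={cs.length} distance constraints (i j dmin dmax confidence)\n")
        for e in cs.entries:
            fh.write(f"{e.i + 1} {e.j + 1} {e.dmin:g} {e.dmax:g} {e.confidence:.6f}\n")


def read_rr_constraints(path) -> ConstraintSet:
    """Read back a constraint file; the tag is recovered from the range."""
    entries = []
    length = None
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
                dmin, dmax, conf = float(toks[2]), float(toks[3]), float(toks[4])
            except (ValueError, IndexError):
                raise FormatError(f"{path}: line {lineno}: malformed constraint") from None
            tag = "beta" if (dmin, dmax) == BETA_RANGE else "general"
            entries.append(Constraint(i, j, dmin, dmax, conf, tag))
    if length is None:
        length = max((max(e.i, e.j) for e in entries), default=0) + 1
    return ConstraintSet(length=length, entries=entries)
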