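"""Sequence-based miRNA binding-site prediction.

A candidate site is a local duplex between a miRNA and a stretch of the
target transcript, scored in two independent ways:

* an affine-gap Smith-Waterman alignment of the reversed miRNA
  (3'->5') against the target (5'->3'), with complementarity rather
  than identity as the match criterion, G:U wobbles partially rewarded,
  and the miRNA seed region (positions 2-8) weighted up -- the scoring
  style of miRanda;
* a nearest-neighbour free-energy estimate of the resulting duplex,
  summing Watson-Crick/wobble stacking energies over consecutive paired
  columns plus a duplex-initiation penalty -- the quantity RNAhybrid-
  class tools threshold.

A (miRNA, target) pair is reported when at least one site clears both
the alignment-score floor (score > 160 by default) and the energy
ceiling (dG <= -30 kcal/mol by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from cernet.errors import ValidationError

RNA_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_BASES)}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: Watson-Crick complementary index pairs and G:U wobbles.
_WC_PAIRS = {(0, 3), (3, 0), (1, 2), (2, 1)}
_WOBBLE_PAIRS = {(2, 3), (3, 2)}

GAP = "-"


def clean_rna(seq: str, name: str = "sequence") -> str:
    """Uppercase, transcribe DNA (T->U) with a warning, validate alphabet."""
    s = seq.strip().upper()
    if "T" in s:
        warnings.warn(f"{name}: DNA alphabet detected; transcribing T->U", stacklevel=3)
        s = s.replace("T", "U")
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise ValidationError(f"{name}: non-RNA characters {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment weights and reporting thresholds.

    The two thresholds (``score_min`` 160, ``energy_max_kcal`` -30)
    define site acceptance; the internal weights follow the miRanda
    family: +5 complementary match, +2 G:U wobble, -3 mismatch, affine
    gaps -9/-4, and substitution scores in the miRNA seed (positions
    ``seed_start``..``seed_end``, 1-based from the 5' end) scaled by
    ``seed_weight``.  The default seed scale of 4 makes a perfect 22-nt
    duplex score 215, comfortably above the 160 floor.
    """

    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_start: int = 2
    seed_end: int = 8
    seed_weight: float = 4.0
    score_min: float = 160.0
    energy_max_kcal: float = -30.0

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValidationError("gap penalties must be negative")
        if self.score_min <= 0:
            raise ValidationError("score_min must be positive")
        if not 1 <= self.seed_start <= self.seed_end:
            raise ValidationError("seed positions must satisfy 1 <= start <= end")

    def pair_score(self, mirna_base: str, target_base: str, mirna_position: int) -> float:
        """Score one aligned column; mirna_position is 1-based from the 5' end."""
        pair = (_BASE_INDEX[mirna_base], _BASE_INDEX[target_base])
        if pair in _WC_PAIRS:
            s = self.match
        elif pair in _WOBBLE_PAIRS:
            s = self.wobble
        else:
            s = self.mismatch
        if self.seed_start <= mirna_position <= self.seed_end:
            s *= self.seed_weight
        return s


@dataclass(frozen=True)
class DuplexSite:
    """One predicted binding site with its alignment and both scores.

    ``aligned_mirna`` is written 3'->5' so it lines up column-for-column
    with ``aligned_target`` (5'->3'); ``pairing`` marks '|' for
    Watson-Crick pairs, ':' for G:U wobbles and ' ' otherwise.
    Coordinates are 1-based inclusive on the given strand.
    """

    mirna_id: str
    target_id: str
    target_class: str
    target_start: int
    target_end: int
    mirna_start: int
    mirna_end: int
    aligned_mirna: str
    pairing: str
    aligned_target: str
    score: float
    energy: float


@dataclass(frozen=True)
class TargetPair:
    """A (miRNA, target) pair with >= 1 site passing both thresholds."""

    mirna_id: str
    target_id: str
    target_class: str
    best_site: DuplexSite
    n_sites: int


# ---------------------------------------------------------------------------
# Nearest-neighbour duplex energy
# ---------------------------------------------------------------------------

#: Stacking free energies dG37 (kcal/mol) for RNA/RNA dinucleotide steps,
#: keyed "t1t2/m1m2": top strand 5'-t1 t2-3', bottom strand 3'-m1 m2-5',
#: with m_i paired to t_i.  Watson-Crick values follow the standard
#: Turner-group nearest-neighbour set (Xia et al. 1998); wobble-containing
#: steps are Turner-style values rounded to the published order of
#: magnitude.  Steps are only summed over consecutive paired columns.
_WC_STACKS: dict[str, float] = {
    "AA/UU": -0.93, "AU/UA": -1.10, "AC/UG": -2.24, "AG/UC": -2.08,
    "UA/AU": -1.33, "UU/AA": -0.93, "UC/AG": -2.35, "UG/AC": -2.11,
    "CA/GU": -2.11, "CU/GA": -2.08, "CC/GG": -3.26, "CG/GC": -2.36,
    "GA/CU": -2.35, "GU/CA": -2.24, "GC/CG": -3.42, "GG/CC": -3.26,
}
_WOBBLE_STACKS: dict[str, float] = {
    # one strand contributes a G:U pair; rotational images filled below
    "AG/UU": -0.55, "AU/UG": -1.36, "CG/GU": -1.41, "CU/GG": -2.11,
    "GG/CU": -1.53, "GU/CG": -2.51, "UG/AU": -1.00, "UU/AG": -1.36,
    "GA/UU": -1.27, "GC/UG": -2.15, "GG/UC": -1.80, "GU/UA": -1.00,
    "UA/GU": -1.36, "UC/GG": -1.80, "UG/GC": -2.15, "UU/GA": -1.27,
    # tandem wobbles
    "GG/UU": -0.50, "GU/UG": +1.29, "UG/GU": +0.30, "UU/GG": -0.50,
}
STACK_TABLE: dict[str, float] = {**_WC_STACKS, **_WOBBLE_STACKS}
# fill rotational symmetry: 5'XY/3'WZ == 5'ZW/3'YX
for _key, _val in list(STACK_TABLE.items()):
    _top, _bot = _key.split("/")
    _rot = f"{_bot[1]}{_bot[0]}/{_top[1]}{_top[0]}"
    STACK_TABLE.setdefault(_rot, _val)

#: Duplex initiation penalty (kcal/mol), Turner-style.
INITIATION_DG = 4.09


def _is_paired(mirna_base: str, target_base: str) -> bool:
    if GAP in (mirna_base, target_base):
        return False
    pair = (_BASE_INDEX[mirna_base], _BASE_INDEX[target_base])
    return pair in _WC_PAIRS or pair in _WOBBLE_PAIRS


def pairing_line(aligned_mirna: str, aligned_target: str) -> str:
    out = []
    for m, t in zip(aligned_mirna, aligned_target):
        if GAP in (m, t):
            out.append(" ")
        elif (_BASE_INDEX[m], _BASE_INDEX[t]) in _WC_PAIRS:
            out.append("|")
        elif (_BASE_INDEX[m], _BASE_INDEX[t]) in _WOBBLE_PAIRS:
            out.append(":")
        else:
            out.append(" ")
    return "".join(out)


def duplex_energy(site: DuplexSite, stack_table: Mapping[str, float] | None = None,
                  initiation: float = INITIATION_DG) -> float:
    """Nearest-neighbour free energy (kcal/mol) of a site's duplex.

    Sums stacking energies over every pair of consecutive aligned
    columns in which both columns are paired (Watson-Crick or wobble);
    unpaired and gapped columns contribute nothing.  The constant
    duplex-initiation penalty is always added, so an alignment with no
    stacked pairs costs exactly the initiation energy.
    """
    table = STACK_TABLE if stack_table is None else stack_table
    total = initiation
    tgt, mir = site.aligned_target, site.aligned_mirna
    for k in range(len(tgt) - 1):
        if _is_paired(mir[k], tgt[k]) and _is_paired(mir[k + 1], tgt[k + 1]):
            key = f"{tgt[k]}{tgt[k+1]}/{mir[k]}{mir[k+1]}"
            total += table.get(key, 0.0)
    return float(total)


def perfect_duplex_energy(mirna_seq: str) -> float:
    """Energy of the miRNA's perfect Watson-Crick duplex (all positions paired)."""
    m = clean_rna(mirna_seq, "miRNA")
    target = reverse_complement(m)
    rev = m[::-1]
    site = DuplexSite("m", "t", "mRNA", 1, len(target), 1, len(m),
                      rev, pairing_line(rev, target), target, 0.0, 0.0)
    return duplex_energy(site)


# ---------------------------------------------------------------------------
# Affine-gap local alignment (Gotoh) of reversed miRNA vs target
# ---------------------------------------------------------------------------

_NEG = -1e30


def _fill_gotoh_python(sub: np.ndarray, gap_open: float, gap_extend: float):
    m, n = sub.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub[i - 1, j - 1], E[i, j], F[i, j])
    return H, E, F


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _fill_gotoh = njit(cache=True)(_fill_gotoh_python)
except Exception:  # pragma: no cover
    _fill_gotoh = _fill_gotoh_python


def _substitution_matrix(mirna_rev: str, target: str, scheme: ScoringScheme) -> np.ndarray:
    """Per-cell substitution scores; row i is reversed-miRNA index i."""
    L = len(mirna_rev)
    base = np.full((4, 4), scheme.mismatch)
    for a, b in _WC_PAIRS:
        base[a, b] = scheme.match
    for a, b in _WOBBLE_PAIRS:
        base[a, b] = scheme.wobble
    mir_idx = np.array([_BASE_INDEX[b] for b in mirna_rev], dtype=np.intp)
    tgt_idx = np.array([_BASE_INDEX[b] for b in target], dtype=np.intp)
    sub = base[mir_idx][:, tgt_idx].astype(float)
    # reversed row i corresponds to 5'-based miRNA position L - i
    positions = L - np.arange(L)
    seed = (positions >= scheme.seed_start) & (positions <= scheme.seed_end)
    sub[seed, :] *= scheme.seed_weight
    return sub


def _traceback(H, E, F, sub, scheme, i, j):
    """Recover one local alignment ending at (i, j); returns
    (i0, j0, mirna_cols, target_cols) where cols are lists of row/col
    indices or None for gaps."""
    mir_cols: list[int | None] = []
    tgt_cols: list[int | None] = []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0.0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                mir_cols.append(i - 1)
                tgt_cols.append(j - 1)
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in miRNA, target base consumed
            mir_cols.append(None)
            tgt_cols.append(j - 1)
            if E[i, j] == H[i, j - 1] + scheme.gap_open:
                state = "H"
            j -= 1
        else:  # gap in target, miRNA base consumed
            mir_cols.append(i - 1)
            tgt_cols.append(None)
            if F[i, j] == H[i - 1, j] + scheme.gap_open:
                state = "H"
            i -= 1
    mir_cols.reverse()
    tgt_cols.reverse()
    return i, j, mir_cols, tgt_cols


def align_duplex(
    mirna_seq: str,
    target_seq: str,
    scheme: ScoringScheme | None = None,
    mirna_id: str = "miRNA",
    target_id: str = "target",
    target_class: str = "mRNA",
    min_report_score: float = 0.0,
) -> list[DuplexSite]:
    """Find local duplex sites of a miRNA on a target sequence.

    The reversed miRNA (3'->5') is locally aligned against the target
    (5'->3') under the scheme's complementarity weights.  Sites with
    score > max(0, ``min_report_score``) are reported greedily by
    descending score with non-overlapping target intervals, each
    annotated with its nearest-neighbour duplex energy.  Deterministic:
    ties break on smaller target start.
    """
    scheme = scheme or ScoringScheme()
    mirna = clean_rna(mirna_seq, f"miRNA {mirna_id}")
    target = clean_rna(target_seq, f"target {target_id}")
    if not mirna or not target:
        return []
    mirna_rev = mirna[::-1]
    L = len(mirna)
    sub = _substitution_matrix(mirna_rev, target, scheme)
    H, E, F = _fill_gotoh(sub, scheme.gap_open, scheme.gap_extend)

    floor = max(0.0, float(min_report_score))
    cells = np.argwhere(H > floor)
    if cells.size == 0:
        return []
    order = np.lexsort((cells[:, 0], cells[:, 1], -H[cells[:, 0], cells[:, 1]]))
    taken: list[tuple[int, int]] = []
    sites: list[DuplexSite] = []
    for idx in order:
        i, j = int(cells[idx, 0]), int(cells[idx, 1])
        score = float(H[i, j])
        i0, j0, mir_cols, tgt_cols = _traceback(H, E, F, sub, scheme, i, j)
        start, end = j0 + 1, j  # 1-based inclusive target interval
        if any(not (end < s or start > e) for s, e in taken):
            continue
        aligned_m = "".join(GAP if c is None else mirna_rev[c] for c in mir_cols)
        aligned_t = "".join(GAP if c is None else target[c] for c in tgt_cols)
        mirna_positions = [L - c for c in mir_cols if c is not None]
        site = DuplexSite(
            mirna_id=mirna_id, target_id=target_id, target_class=target_class,
            target_start=start, target_end=end,
            mirna_start=min(mirna_positions), mirna_end=max(mirna_positions),
            aligned_mirna=aligned_m, pairing=pairing_line(aligned_m, aligned_t),
            aligned_target=aligned_t, score=score, energy=0.0,
        )
        site = replace(site, energy=duplex_energy(site))
        sites.append(site)
        taken.append((start, end))
    sites.sort(key=lambda s: (-s.score, s.target_start))
    return sites


def rescore_alignment(site: DuplexSite, scheme: ScoringScheme | None = None) -> float:
    """Recompute a site's alignment score from its stored alignment.

    Walks the aligned strings column by column, applying substitution
    weights (seed positions scaled) and affine gap costs; used to check
    the invariant that stored scores are reproducible.
    """
    scheme = scheme or ScoringScheme()
    total = 0.0
    # leftmost aligned miRNA base is the highest miRNA position (3'->5')
    pos = site.mirna_end
    gap_run = False
    for m, t in zip(site.aligned_mirna, site.aligned_target):
        if m == GAP or t == GAP:
            total += scheme.gap_extend if gap_run else scheme.gap_open
            gap_run = True
            if m != GAP:
                pos -= 1
        else:
            total += scheme.pair_score(m, t, pos)
            pos -= 1
            gap_run = False
    return total


# ---------------------------------------------------------------------------
# FASTA handling and pair prediction
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> RNA sequence mapping."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"{path}: duplicate FASTA id '{record.id}'")
        seqs[record.id] = clean_rna(str(record.seq), record.id)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k:k + width] + "\n")


def predict_targets(
    mirnas: Mapping[str, str] | str | Path,
    targets: Mapping[str, str] | str | Path,
    scheme: ScoringScheme | None = None,
    target_class: str = "mRNA",
) -> list[TargetPair]:
    """All (miRNA, target) pairs with a site passing both thresholds.

    ``mirnas`` and ``targets`` may be FASTA paths or id -> sequence
    mappings.  A pair is reported when >= 1 site has score >
    ``scheme.score_min`` and energy <= ``scheme.energy_max_kcal``;
    ``best_site`` maximises score with ties broken by lower energy then
    smaller target start.  Output is sorted (mirna_id, target_id).
    """
    scheme = scheme or ScoringScheme()
    if not isinstance(mirnas, Mapping):
        mirnas = read_fasta(mirnas)
    if not isinstance(targets, Mapping):
        targets = read_fasta(targets)
    for mid, seq in mirnas.items():
        if not 18 <= len(seq) <= 26:
            warnings.warn(f"miRNA {mid}: length {len(seq)} outside the typical 18-26 nt range",
                          stacklevel=2)
    pairs: list[TargetPair] = []
    for mid in sorted(mirnas):
        for tid in sorted(targets):
            sites = align_duplex(mirnas[mid], targets[tid], scheme,
                                 mirna_id=mid, target_id=tid, target_class=target_class,
                                 min_report_score=scheme.score_min)
            passing = [s for s in sites
                       if s.score > scheme.score_min and s.energy <= scheme.energy_max_kcal]
            if passing:
                best = min(passing, key=lambda s: (-s.score, s.energy, s.target_start))
                pairs.append(TargetPair(mid, tid, target_class, best, len(passing)))
    return pairs
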