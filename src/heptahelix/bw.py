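"""Ballesteros-Weinstein (BW) generic numbering anchored at conserved motifs.

Class A GPCR helices carry one highly conserved position each, labelled x.50;
every other residue in a helix is numbered by its plain sequence offset from
that anchor (label = helix.(50 + n - anchor)). Anchors are located from the
conserved sequence motifs:

* TM2: N-[LIVMF]-x-x-x-D, the D is 2.50
* TM3: [ED]-R-[YW], the R is 3.50 (the E/DRY or ERW box)
* TM6: C-[WMF]-x-P, the P is 6.50 (CWxP; CMxP in glycoprotein-hormone receptors)
* TM7: N-P-x-x-Y, the P is 7.50 (so N = 7.49, Y = 7.53)
* TM1: the conserved Asn (1.50), TM4: the conserved Trp (4.50) -- taken as the
  unique N/W inside the annotated helix, overridable
* TM5: the conserved Pro (5.50); glycoprotein-hormone receptors carry an Ala
  here instead, so 5.50 must then be supplied as an override

No bulge/insertion labels are used: plain arithmetic offsets only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import AnchorInferenceError, LabelRangeError
from .structure_io import TMAnnotation

__all__ = [
    "MotifHit", "AnchorSet", "BWMap",
    "MOTIF_PATTERNS", "scan_motifs", "infer_anchors", "assign_bw",
    "read_sequence",
]

# motif name -> (regex on one-letter sequence, expected helix, offset of the
# anchor within the match, anchor helix index or None if the motif carries none)
MOTIF_PATTERNS: dict[str, tuple[str, str, int, int | None]] = {
    "NLxxxD": (r"N[LIVMF]...D", "TM2", 5, 2),
    "DRY_ERW": (r"[ED]R[YW]", "TM3", 1, 3),
    "CWxP_CMxP": (r"C[WMF].P", "TM6", 3, 6),
    "NPxxY": (r"NP..Y", "TM7", 1, 7),
}


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int          # author number of first matched residue
    end: int            # author number of last matched residue
    matched: str
    expected_helix: str
    in_expected_helix: bool | None = None  # None when no annotation given


@dataclass(frozen=True)
class AnchorSet:
    """Author residue number carrying the x.50 label, per helix 1..7."""

    anchors: dict[int, int]

    def __post_init__(self):
        missing = [h for h in range(1, 8) if h not in self.anchors]
        if missing:
            raise AnchorInferenceError(
                f"anchor set incomplete: missing helices {missing}")

    def __getitem__(self, helix: int) -> int:
        return self.anchors[helix]

    def items(self):
        return self.anchors.items()


def read_sequence(path) -> tuple[str, list[int]]:
    """Read a single-record FASTA; author numbering from a ``start=N`` header tag.

    Header example: ``>TSHR_TMD start=409``. Without the tag, numbering
    starts at 1.
    """
    path = Path(path)
    header = None
    seq_parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    break  # first record only
                header = line
            else:
                seq_parts.append(line)
    seq = "".join(seq_parts).upper()
    start = 1
    if header:
        m = re.search(r"start=(\d+)", header)
        if m:
            start = int(m.group(1))
    return seq, list(range(start, start + len(seq)))


def _index_of(numbering: list[int], number: int) -> int:
    return numbering.index(number)


def scan_motifs(sequence: str, numbering: list[int] | None = None,
                annotation: TMAnnotation | None = None) -> list[MotifHit]:
    """All hits of the conserved class-A motifs in a numbered sequence.

    Overlapping occurrences are all reported. With an annotation, each hit is
    flagged by whether it falls inside its expected helix range.
    """
    if numbering is None:
        numbering = list(range(1, len(sequence) + 1))
    if len(numbering) != len(sequence):
        raise ValueError("numbering must align index-by-index with sequence")
    hits: list[MotifHit] = []
    for name, (pattern, helix, _off, _anchor) in MOTIF_PATTERNS.items():
        for m in re.finditer(f"(?=({pattern}))", sequence):
            matched = m.group(1)
            start_n = numbering[m.start()]
            end_n = numbering[m.start() + len(matched) - 1]
            inside = None
            if annotation is not None and helix in annotation.helices:
                lo, hi = annotation.helix_range(helix)
                inside = lo <= start_n and end_n <= hi
            hits.append(MotifHit(name, start_n, end_n, matched, helix, inside))
    hits.sort(key=lambda h: (h.motif_name, h.start))
    return hits


def _pick_hit(hits: list[MotifHit], motif: str) -> MotifHit | None:
    cand = [h for h in hits if h.motif_name == motif]
    if not cand:
        return None
    inside = [h for h in cand if h.in_expected_helix]
    pool = inside or cand
    if len(pool) > 1:
        warnings.warn(
            f"multiple {motif} hits at {[h.start for h in pool]}; using the first",
            stacklevel=3)
    return min(pool, key=lambda h: h.start)


def _unique_letter_anchor(sequence: str, numbering: list[int],
                          annotation: TMAnnotation, helix_name: str,
                          letter: str) -> int | None:
    if helix_name not in annotation.helices:
        return None
    lo, hi = annotation.helix_range(helix_name)
    positions = [numbering[i] for i, aa in enumerate(sequence)
                 if aa == letter and lo <= numbering[i] <= hi]
    if len(positions) == 1:
        return positions[0]
    if len(positions) > 1:
        warnings.warn(
            f"{helix_name}: {len(positions)} candidate '{letter}' residues "
            f"{positions}; supply an anchor override", stacklevel=3)
    return None


def infer_anchors(sequence: str, numbering: list[int],
                  annotation: TMAnnotation,
                  overrides: dict[int, int] | None = None) -> AnchorSet:
    """Locate the x.50 anchor of every helix from motifs and the annotation.

    ``overrides`` maps helix index -> author number and wins over inference;
    the annotation's own ``anchor_overrides`` (keys like ``"5.50"``) are also
    honoured. A helix whose anchor cannot be determined raises
    :class:`AnchorInferenceError` naming the helix.
    """
    overrides = dict(overrides or {})
    for key, num in annotation.anchor_overrides.items():
        helix = int(str(key).split(".")[0])
        overrides.setdefault(helix, num)

    hits = scan_motifs(sequence, numbering, annotation)
    anchors: dict[int, int] = {}

    for motif, (_pat, _helix, offset, helix_idx) in MOTIF_PATTERNS.items():
        if helix_idx in overrides:
            continue
        hit = _pick_hit(hits, motif)
        if hit is not None:
            idx = _index_of(numbering, hit.start)
            anchors[helix_idx] = numbering[idx + offset]

    # TM1 (N1.50), TM4 (W4.50), TM5 (P5.50 -- often absent in GPHRs)
    for helix_idx, helix_name, letter in ((1, "TM1", "N"), (4, "TM4", "W"),
                                          (5, "TM5", "P")):
        if helix_idx in overrides:
            continue
        found = _unique_letter_anchor(sequence, numbering, annotation,
                                      helix_name, letter)
        if found is not None:
            anchors[helix_idx] = found

    anchors.update(overrides)

    missing = [h for h in range(1, 8) if h not in anchors]
    if missing:
        raise AnchorInferenceError(
            "cannot infer x.50 anchor for "
            + ", ".join(f"TM{h}" for h in missing)
            + "; supply an override")
    # sanity: anchor inside its helix range when annotated
    for helix_idx, num in anchors.items():
        name = f"TM{helix_idx}"
        if name in annotation.helices:
            lo, hi = annotation.helix_range(name)
            if not lo <= num <= hi:
                raise AnchorInferenceError(
                    f"{name} anchor {num} lies outside annotated range {lo}-{hi}")
    return AnchorSet(anchors)


class BWMap:
    """Bidirectional author number <-> BW label map over annotated helices."""

    def __init__(self, annotation: TMAnnotation, anchors: AnchorSet):
        self.annotation = annotation
        self.anchors = anchors
        self._num_to_label: dict[int, str] = {}
        self._label_to_num: dict[str, int] = {}
        for helix_idx in range(1, 8):
            name = f"TM{helix_idx}"
            if name not in annotation.helices:
                continue
            anchor = anchors[helix_idx]
            for num in annotation.numbers(name):
                pos = 50 + num - anchor
                if not 1 <= pos <= 99:
                    raise LabelRangeError(
                        f"{name} residue {num}: position {pos} outside 1..99 "
                        f"(anchor {anchor})")
                label = f"{helix_idx}.{pos}"
                self._num_to_label[num] = label
                self._label_to_num[label] = num

    def label_of(self, number: int) -> str | None:
        return self._num_to_label.get(number)

    def number_of(self, label: str) -> int | None:
        return self._label_to_num.get(str(label))

    @property
    def chain_id(self) -> str:
        return self.annotation.chain_id

    def labels(self) -> dict[int, str]:
        return dict(self._num_to_label)

    def helix_of_label(self, label: str) -> str:
        return "TM" + str(label).split(".")[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\thelix\tlabel\n")
            for num in sorted(self._num_to_label):
                label = self._num_to_label[num]
                fh.write(f"{num}\t{self.helix_of_label(label)}\t{label}\n")

    def __len__(self) -> int:
        return len(self._num_to_label)


def assign_bw(annotation: TMAnnotation, anchors: AnchorSet) -> BWMap:
    """Build the BW map for every residue of every annotated helix."""
    return BWMap(annotation, anchors)
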