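"""Per-residue attribute files for molecular-graphics coloring.

Segment-level scores (e.g. SCCC per secondary-structure element) are
exported as a residue attribute file in the widely used
``attribute:``/``recipient:`` text dialect, so a viewer can color a fitted
model by local fit quality.  A generic TSV (chain, resnum, value) is also
available for other consumers.
"""

from __future__ import annotations

import os
import warnings

from .structure_core import AtomicStructure, SegmentSelection


def _resolve_residues(
    model: AtomicStructure,
    segment_scores: dict[str, float],
    segments: list[SegmentSelection],
) -> list[tuple[str, int, float]]:
    """(chain, resnum, value) per covered residue, later segments winning."""
    by_label = {s.label: s for s in segments}
    for label in segment_scores:
        if label not in by_label:
            raise ValueError(f"segment {label!r} not among the provided selections")
    residues = sorted(
        {(a.chain, a.res_seq) for a in model.atoms}, key=lambda t: (t[0], t[1])
    )
    assigned: dict[tuple[str, int], float] = {}
    seen: set[tuple[str, int]] = set()
    for label, value in segment_scores.items():
        sel = by_label[label]
        sel_res = [
            r
            for r in residues
            if any(r[0] == ch and lo <= r[1] <= hi for ch, lo, hi in sel.ranges)
        ]
        if not sel_res:
            raise ValueError(f"segment {label!r} matches no residue of the model")
        overlap = seen.intersection(sel_res)
        if overlap:
            warnings.warn(
                f"segment {label!r} overlaps {len(overlap)} residue(s) already "
                "assigned; last-listed segment wins",
                stacklevel=2,
            )
        for r in sel_res:
            assigned[r] = value
            seen.add(r)
    return [(ch, num, assigned[(ch, num)]) for ch, num in sorted(assigned)]


def write_attributes(
    model: AtomicStructure,
    segment_scores: dict[str, float],
    segments: list[SegmentSelection],
    path: str | os.PathLike,
    attribute_name: str = "segment_score",
) -> None:
    """Write a residue attribute file mapping each covered residue to its
    segment's score.  Residues covered by several segments receive the
    last-listed segment's value (with a warning)."""
    rows = _resolve_residues(model, segment_scores, segments)
    with open(os.fspath(path), "w") as fh:
        fh.write(f"attribute: {attribute_name}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for chain, resnum, value in rows:
            fh.write(f"\t/{chain}:{resnum}\t{value:.6g}\n")


def write_attributes_tsv(
    model: AtomicStructure,
    segment_scores: dict[str, float],
    segments: list[SegmentSelection],
    path: str | os.PathLike,
) -> None:
    """Generic alternative output: chain, resnum, value (tab-separated)."""
    rows = _resolve_residues(model, segment_scores, segments)
    with open(os.fspath(path), "w") as fh:
        fh.write("chain\tresnum\tvalue\n")
        for chain, resnum, value in rows:
            fh.write(f"{chain}\t{resnum}\t{value:.6g}\n")
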