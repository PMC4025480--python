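"""Detection of recombination-suppressed blocks (putative inversions).

An inversion segregating in the cross suppresses crossover recovery in
heterozygotes, so many physically dispersed markers collapse to (nearly)
one genetic position. The detector formalises that signature: maximal runs
of consecutive map markers whose total genetic span stays within a small
``eps_cM``, gated on a minimum marker count and a minimum physical extent.
Physical extent across several scaffolds is the sum of each scaffold's
marker extent ("at least" semantics, since inter-scaffold gaps are
unknown).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rilmap.linkmap import GeneticMap


def detect_blocks(
    gmap: GeneticMap,
    eps_cM: float = 1.0,
    min_markers: int = 20,
    min_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Find non-overlapping suppressed blocks on every linkage group.

    Scans each group's ordered markers with a two-pointer sweep: from each
    start, the run extends right while the cM span stays ≤ ``eps_cM``; runs
    passing both gates are emitted and the sweep resumes past them, so calls
    never overlap. Detection is invariant to reversing a group's marker
    order.
    """
    rows = []
    tab = gmap.marker_table()
    for grp in gmap.groups:
        pos = np.asarray(grp.positions_cM, dtype=float)
        if len(pos) and pos[0] > pos[-1]:  # tolerate reversed maps
            pos = pos[::-1].copy()
            ids = grp.marker_ids[::-1]
        else:
            ids = grp.marker_ids
        if np.any(np.diff(pos) < 0):
            order = np.argsort(pos, kind="stable")
            pos, ids = pos[order], ids[order]
        sub = tab[tab["group"] == grp.group_id]
        meta = sub.set_index("marker_id")
        i = 0
        n = len(pos)
        while i < n:
            j = int(np.searchsorted(pos, pos[i] + eps_cM, side="right")) - 1
            if j - i + 1 >= min_markers:
                run = ids[i : j + 1]
                span_bp = _physical_span(meta.loc[run])
                if span_bp >= min_bp:
                    scafs = sorted(set(meta.loc[run, "scaffold_id"]))
                    rows.append(
                        (
                            grp.group_id,
                            int(run[0]),
                            int(run[-1]),
                            len(run),
                            int(span_bp),
                            float(pos[j] - pos[i]),
                            ",".join(map(str, scafs)),
                        )
                    )
                    i = j + 1
                    continue
            i += 1
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "first_marker",
            "last_marker",
            "n_markers",
            "physical_span_bp",
            "map_span_cM",
            "scaffolds",
        ],
    )


def _physical_span(meta: pd.DataFrame) -> int:
    span = 0
    for _, sub in meta.groupby("scaffold_id"):
        span += int(sub["end"].max() - sub["start"].min())
    return span


def block_report(calls: pd.DataFrame, gmap: GeneticMap) -> pd.DataFrame:
    """Per-block summary with flanking map gaps.

    The flanking gap is the cM distance from the block's edge marker to its
    nearest neighbour outside the block — large gaps are the classic
    signature flanking an inversion. Blocks at a group end report a single
    gap (NaN for the absent side).
    """
    rows = []
    for _, call in calls.iterrows():
        grp = next(g for g in gmap.groups if g.group_id == call["group"])
        ids = list(grp.marker_ids)
        i0 = ids.index(call["first_marker"])
        i1 = ids.index(call["last_marker"])
        if i0 > i1:
            i0, i1 = i1, i0
        pos = grp.positions_cM
        gap_left = float(pos[i0] - pos[i0 - 1]) if i0 > 0 else np.nan
        gap_right = float(pos[i1 + 1] - pos[i1]) if i1 + 1 < len(pos) else np.nan
        rows.append(
            (
                call["group"],
                call["n_markers"],
                call["physical_span_bp"],
                call["map_span_cM"],
                gap_left,
                gap_right,
                ",".join(str(int(m)) for m in grp.marker_ids[i0 : i1 + 1]),
                call["scaffolds"],
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "n_markers",
            "physical_span_bp",
            "map_span_cM",
            "flank_gap_left_cM",
            "flank_gap_right_cM",
            "markers",
            "scaffolds",
        ],
    )


def blocks_to_bed(calls: pd.DataFrame, gmap: GeneticMap, path: str) -> None:
    """BED-like export of the windows involved in each detected block."""
    tab = gmap.marker_table().set_index("marker_id")
    with open(path, "w") as fh:
        for k, call in calls.iterrows():
            grp = next(g for g in gmap.groups if g.group_id == call["group"])
            ids = list(grp.marker_ids)
            i0 = ids.index(call["first_marker"])
            i1 = ids.index(call["last_marker"])
            if i0 > i1:
                i0, i1 = i1, i0
            for m in grp.marker_ids[i0 : i1 + 1]:
                meta = tab.loc[int(m)]
                fh.write(
                    f"{meta['scaffold_id']}\t{meta['start']}\t{meta['end']}\tblock{k}\n"
                )
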