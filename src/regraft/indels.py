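"""Detection of taxon-group-specific gap blocks (indel synapomorphies).

A shared insertion/deletion is treated as character evidence of common
ancestry: if every member of two taxon groups lacks the same alignment
interval while other groups retain it, the gap block supports grouping
them.  The scanner formalises "the same interval" as per-taxon maximal
gap runs whose start and end coordinates agree within a configurable
slack, and reports which named groups are entirely inside, and which
entirely outside, each clustered block.  Block coordinates can also be
reported in the residue numbering of a designated reference taxon.

No significance statistic is attached: there is no null model of indel
evolution here, only the descriptive signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alignment import GAP, Alignment, map_to_reference


class IndelError(ValueError):
    pass


@dataclass(frozen=True)
class GapRun:
    """A maximal run of gap columns in one taxon's row, [start, end)."""

    taxon: str
    start: int
    end: int


@dataclass
class GapBlock:
    """A cluster of near-identical gap runs shared by several taxa."""

    start: int
    end: int
    taxa: tuple[str, ...]
    ref_start: int | None = None
    ref_end: int | None = None


@dataclass
class GroupSignal:
    """A gap block with its per-group presence/absence summary."""

    block: GapBlock
    present_groups: tuple[str, ...]
    absent_groups: tuple[str, ...]
    purity: dict[str, float]
    kind: str  # "deletion-like" if a minority of taxa carry the gap


def find_gap_blocks(aln: Alignment) -> list[GapRun]:
    """Per-taxon maximal runs of consecutive gap columns."""
    runs = []
    for taxon, row in zip(aln.taxa, aln.rows):
        start = None
        for j, ch in enumerate(row):
            if ch == GAP:
                if start is None:
                    start = j
            elif start is not None:
                runs.append(GapRun(taxon, start, j))
                start = None
        if start is not None:
            runs.append(GapRun(taxon, start, len(row)))
    return runs


def _cluster_runs(runs: list[GapRun], slack: int) -> list[list[GapRun]]:
    """Group runs whose boundaries agree within slack at both ends.

    Clusters grow greedily around each run in (start, end) order; each run
    joins the first cluster whose *seed* run it agrees with, which keeps
    the result independent of taxon order.
    """
    clusters: list[list[GapRun]] = []
    for run in sorted(runs, key=lambda r: (r.start, r.end, r.taxon)):
        for cl in clusters:
            seed = cl[0]
            if abs(run.start - seed.start) <= slack and abs(run.end - seed.end) <= slack:
                cl.append(run)
                break
        else:
            clusters.append([run])
    return clusters


def group_specific_blocks(
    aln: Alignment,
    groups: dict[str, list[str] | tuple[str, ...]],
    min_len: int = 2,
    boundary_slack: int = 1,
    ref_taxon: str | None = None,
) -> list[GroupSignal]:
    """Gap blocks fully shared by some named groups and fully absent from
    others.

    Per-taxon gap runs are clustered by boundary agreement within
    ``boundary_slack`` columns; for each cluster spanning at least
    ``min_len`` columns the groups are classified as "present" (every
    member has a clustered run), "absent" (no member does) or mixed.
    Only clusters with at least one present and one absent group are
    reported.  ``purity`` records the conforming fraction per group.
    """
    if min_len < 1:
        raise IndelError("min_len must be >= 1")
    seen: dict[str, str] = {}
    for g, members in groups.items():
        for t in members:
            if t in seen:
                raise IndelError(f"taxon {t!r} in both groups {seen[t]!r} and {g!r}")
            if t not in aln.taxa:
                raise IndelError(f"group {g!r} member {t!r} not in alignment")
            seen[t] = g
    refmap = map_to_reference(aln, ref_taxon) if ref_taxon else None
    clusters = _cluster_runs(find_gap_blocks(aln), boundary_slack)
    signals = []
    for cl in clusters:
        start = min(r.start for r in cl)
        end = max(r.end for r in cl)
        if end - start < min_len:
            continue
        carriers = {r.taxon for r in cl}
        present, absent, purity = [], [], {}
        for g, members in groups.items():
            inside = sum(1 for t in members if t in carriers)
            frac = inside / len(members)
            if inside == len(members):
                present.append(g)
                purity[g] = 1.0
            elif inside == 0:
                absent.append(g)
                purity[g] = 1.0
            else:
                purity[g] = max(frac, 1.0 - frac)
        if not present or not absent:
            continue
        n_present = sum(len(groups[g]) for g in present)
        n_absent = sum(len(groups[g]) for g in absent)
        block = GapBlock(start=start, end=end, taxa=tuple(sorted(carriers)))
        if refmap is not None:
            inref = [refmap[j] for j in range(start, end) if refmap[j] is not None]
            if inref:
                block.ref_start, block.ref_end = inref[0], inref[-1]
        signals.append(
            GroupSignal(
                block=block,
                present_groups=tuple(sorted(present)),
                absent_groups=tuple(sorted(absent)),
                purity=purity,
                kind="deletion-like" if n_present <= n_absent else "insertion-like",
            )
        )
    signals.sort(key=lambda s: (s.block.start, s.block.end))
    return signals


def signals_to_frame(signals: list[GroupSignal]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of the scanner output."""
    return pd.DataFrame(
        {
            "start": [s.block.start for s in signals],
            "end": [s.block.end for s in signals],
            "ref_start": [s.block.ref_start for s in signals],
            "ref_end": [s.block.ref_end for s in signals],
            "kind": [s.kind for s in signals],
            "present_groups": [",".join(s.present_groups) for s in signals],
            "absent_groups": [",".join(s.absent_groups) for s in signals],
            "taxa": [",".join(s.block.taxa) for s in signals],
            "min_purity": [min(s.purity.values()) if s.purity else 1.0 for s in signals],
        }
    )
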