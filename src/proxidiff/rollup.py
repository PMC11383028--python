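"""Razor-peptide protein inference, grouping, and peptide-to-protein roll-up.

Shared (razor) peptides are exclusively assigned to the candidate protein
with the most identified peptides; proteins left with identical peptide
sets are merged into one group represented by a master accession; protein
intensity is the plain sum of its assigned peptides' intensities, so the
total signal per sample is conserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PeptideQuantMatrix, ProteinQuantMatrix
from .errors import ConsistencyError, StateError

logger = logging.getLogger(__name__)


@dataclass
class PeptideProteinMap:
    """Peptide -> protein mapping through its three resolution states.

    ``candidates`` is the raw search-space mapping (>= 1 accession per
    peptide). :func:`assign_razor` fills ``assigned`` (exactly one
    accession per peptide); :func:`group_proteins` fills ``groups`` (one
    row per accession: ``group_id`` and the group's ``master``).
    """

    candidates: dict[str, tuple[str, ...]]
    assigned: pd.Series | None = field(default=None)
    groups: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        for pid, accs in self.candidates.items():
            if len(accs) == 0:
                raise ConsistencyError(f"peptide {pid!r} has zero candidates")

    @property
    def is_resolved(self) -> bool:
        return self.assigned is not None

    @property
    def is_grouped(self) -> bool:
        return self.groups is not None

    def master_of(self, accession: str) -> str:
        if self.groups is None:
            raise StateError("map is not grouped yet")
        return str(self.groups.loc[accession, "master"])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (peptide, candidates, assigned, group, master)."""
        rows = []
        for pid, accs in self.candidates.items():
            assigned = self.assigned.get(pid) if self.assigned is not None else ""
            master = (
                self.master_of(assigned)
                if assigned and self.groups is not None
                else ""
            )
            rows.append({
                "peptide_id": pid,
                "candidates": ";".join(accs),
                "assigned": assigned or "",
                "master": master,
            })
        return pd.DataFrame(rows, columns=["peptide_id", "candidates",
                                           "assigned", "master"])


def assign_razor(
    pmap: PeptideProteinMap, matrix: PeptideQuantMatrix
) -> PeptideProteinMap:
    """Assign every shared peptide to the candidate with the most
    identified peptides (counted over the matrix's surviving peptides);
    ties break to the lexicographically smaller accession.

    The result is a pure function of the (map, peptide set) pair and is
    independent of row order.
    """
    surviving = [str(p) for p in matrix.peptide_ids]
    missing = [p for p in surviving if p not in pmap.candidates]
    if missing:
        raise ConsistencyError(
            f"matrix peptides absent from the map: {missing[:5]}"
        )
    counts: dict[str, int] = {}
    for pid in surviving:
        for acc in pmap.candidates[pid]:
            counts[acc] = counts.get(acc, 0) + 1
    assigned = {}
    for pid in surviving:
        accs = pmap.candidates[pid]
        assigned[pid] = min(accs, key=lambda a: (-counts[a], a))
    return PeptideProteinMap(
        candidates=pmap.candidates,
        assigned=pd.Series(assigned, name="assigned"),
    )


def group_proteins(
    pmap: PeptideProteinMap,
    protein_lengths: dict[str, int] | None = None,
    peptide_lengths: dict[str, int] | None = None,
) -> PeptideProteinMap:
    """Merge proteins with identical assigned peptide sets into groups and
    pick each group's master accession.

    Master selection: highest % coverage (sum of unique assigned peptide
    lengths / protein length) when lengths are supplied for every group
    member; otherwise highest assigned-peptide count; remaining ties break
    lexicographically. Within a group peptide sets are identical, so the
    count criterion only discriminates via the coverage fallback.
    """
    if pmap.assigned is None:
        raise StateError("razor assignment must run before grouping")
    pep_sets: dict[str, frozenset[str]] = {}
    for pid, acc in pmap.assigned.items():
        pep_sets.setdefault(acc, frozenset())
    by_acc: dict[str, set[str]] = {acc: set() for acc in pep_sets}
    for pid, acc in pmap.assigned.items():
        by_acc[acc].add(pid)

    clusters: dict[frozenset[str], list[str]] = {}
    for acc in sorted(by_acc):
        clusters.setdefault(frozenset(by_acc[acc]), []).append(acc)

    def coverage(acc: str, peptides: set[str]) -> float | None:
        if protein_lengths is None or acc not in protein_lengths:
            return None
        total = 0
        for pid in peptides:
            if peptide_lengths and pid in peptide_lengths:
                total += peptide_lengths[pid]
            else:
                total += len(pid)  # peptide id doubles as its sequence
        return total / protein_lengths[acc]

    rows = []
    for gid, (pepset, members) in enumerate(sorted(clusters.items(),
                                                   key=lambda kv: kv[1][0])):
        covs = {acc: coverage(acc, by_acc[acc]) for acc in members}
        if all(c is not None for c in covs.values()):
            master = min(members, key=lambda a: (-covs[a], a))
        else:
            master = min(members, key=lambda a: (-len(by_acc[a]), a))
        for acc in members:
            rows.append({"accession": acc, "group_id": gid, "master": master})
    groups = pd.DataFrame(rows).set_index("accession")
    return PeptideProteinMap(
        candidates=pmap.candidates, assigned=pmap.assigned, groups=groups
    )


def rollup(
    matrix: PeptideQuantMatrix, pmap: PeptideProteinMap
) -> ProteinQuantMatrix:
    """Sum assigned peptide intensities into one row per protein group,
    labeled by the group's master accession."""
    if matrix.stage != "trimmed_normalized":
        raise StateError(f"roll-up expects trimmed_normalized, got {matrix.stage!r}")
    if pmap.assigned is None or pmap.groups is None:
        raise StateError("map must be razor-resolved and grouped before roll-up")
    masters = pmap.assigned.map(pmap.groups["master"])
    masters = masters.loc[[p for p in matrix.peptide_ids]]
    sums = matrix.intensity.groupby(masters.to_numpy()).sum()
    counts = pd.Series(masters.to_numpy()).value_counts().sort_index()
    sums = sums.sort_index()
    sums.index.name = "accession"
    counts.index.name = "accession"
    orphans = set(pmap.groups["master"]) - set(sums.index)
    if orphans:
        logger.info("roll-up: %d protein group(s) had no surviving peptides "
                    "and were excluded", len(orphans))
    return ProteinQuantMatrix(intensity=sums, peptide_counts=counts.rename("n_peptides"))
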