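"""Labelled marker alignment: the target species plus confounder taxa.

The panel is the substrate for diagnostic-window search: one target
record (e.g. the prey species' mitochondrial control region) aligned
against confounder taxa that could cross-amplify, each confounder
flagged for whether its geographic range overlaps the target's (the
overlap class carries a stricter difference threshold downstream).

Labels travel in a sidecar file (YAML mapping or 3-column TSV), not in
FASTA headers, so no header dialect is guessed. All user-facing
coordinates are 1-based inclusive on the ungapped target reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .errors import LengthMismatchError, PanelCompositionError, SpanError
from .sequtils import GAP, NucSequence, read_fasta

ROLE_TARGET = "target"
ROLE_CONFOUNDER = "confounder"


@dataclass(frozen=True)
class PanelRecord:
    id: str
    role: str
    overlaps_target_range: Optional[bool]
    seq: NucSequence


@dataclass(frozen=True)
class AlignedPanel:
    """Validated labelled alignment with exactly one target record."""

    records: tuple[PanelRecord, ...]
    alignment_length: int
    reference_id: str

    @property
    def target(self) -> PanelRecord:
        return next(r for r in self.records if r.role == ROLE_TARGET)

    @property
    def confounders(self) -> tuple[PanelRecord, ...]:
        return tuple(r for r in self.records if r.role == ROLE_CONFOUNDER)

    @property
    def overlapping_confounders(self) -> tuple[PanelRecord, ...]:
        return tuple(r for r in self.confounders if r.overlaps_target_range)

    def ungapped_target(self) -> NucSequence:
        return self.target.seq.ungapped()

    # -- coordinate mapping -------------------------------------------------

    def _target_cumulative(self) -> list[int]:
        res = self.target.seq.residues
        cum, n = [], 0
        for c in res:
            if c != GAP:
                n += 1
            cum.append(n)
        return cum

    def column_to_reference(self, column: int) -> tuple[int, bool]:
        """Map an alignment column (1-based) to the target's ungapped
        reference coordinate (1-based).

        Returns ``(position, is_gap_column)``. Columns where the target
        has a gap map to the position of the preceding target residue
        (0 before the first residue) with the gap flag set.
        """
        if not 1 <= column <= self.alignment_length:
            raise SpanError(
                f"column {column} outside 1..{self.alignment_length}"
            )
        res = self.target.seq.residues
        pos = sum(c != GAP for c in res[:column])
        return pos, res[column - 1] == GAP

    def reference_to_column(self, position: int) -> int:
        """Inverse map: the unique alignment column (1-based) holding the
        target's ungapped residue ``position``."""
        res = self.target.seq.residues
        n = 0
        for col, c in enumerate(res, start=1):
            if c != GAP:
                n += 1
                if n == position:
                    return col
        raise SpanError(
            f"reference position {position} outside 1..{n} of target {self.reference_id}"
        )


LabelMapping = Mapping[str, Mapping[str, object]]


def _read_labels(path: Union[str, Path]) -> LabelMapping:
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PanelCompositionError(f"{path}: label YAML must map id -> fields")
        return raw
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise PanelCompositionError(f"{path}: label TSV needs columns id, role[, overlap]")
    labels: dict[str, dict[str, object]] = {}
    for row in df.itertuples(index=False):
        rid, role = row[0], row[1]
        overlap = row[2] if len(row) > 2 and pd.notna(row[2]) else "0"
        labels[rid] = {"role": role, "overlaps_target_range": str(overlap) in {"1", "true", "True"}}
    return labels


def build_panel(
    sequences: list[NucSequence], labels: LabelMapping
) -> AlignedPanel:
    """Assemble and validate a panel from in-memory sequences and labels."""
    missing = [s.id for s in sequences if s.id not in labels]
    if missing:
        raise PanelCompositionError(
            f"records absent from labels: {', '.join(missing)}"
        )
    lengths = {s.id: len(s) for s in sequences}
    if len(set(lengths.values())) > 1:
        shortest = min(lengths, key=lengths.get)
        longest = max(lengths, key=lengths.get)
        raise LengthMismatchError(
            "ragged alignment: shortest record "
            f"{shortest} ({lengths[shortest]} cols), longest {longest} "
            f"({lengths[longest]} cols)"
        )
    records = []
    for s in sequences:
        lab = labels[s.id]
        role = str(lab.get("role", ""))
        if role not in (ROLE_TARGET, ROLE_CONFOUNDER):
            raise PanelCompositionError(f"{s.id}: unknown role {role!r}")
        overlap = lab.get("overlaps_target_range")
        records.append(
            PanelRecord(
                id=s.id,
                role=role,
                overlaps_target_range=None if role == ROLE_TARGET else bool(overlap),
                seq=s,
            )
        )
    targets = [r for r in records if r.role == ROLE_TARGET]
    if len(targets) != 1:
        raise PanelCompositionError(
            f"panel must contain exactly one target record, found {len(targets)}"
        )
    if not any(r.role == ROLE_CONFOUNDER for r in records):
        raise PanelCompositionError("panel must contain at least one confounder")
    return AlignedPanel(
        records=tuple(records),
        alignment_length=len(sequences[0]),
        reference_id=targets[0].id,
    )


def load_panel(
    alignment_path: Union[str, Path],
    labels: Union[str, Path, LabelMapping],
) -> AlignedPanel:
    """Read an aligned FASTA plus its sidecar labels into an AlignedPanel.

    ``labels`` may be a path to a YAML mapping / 3-column TSV
    (id, role, overlap flag as 0/1) or an equivalent in-memory mapping.
    """
    sequences = read_fasta(alignment_path)
    if not isinstance(labels, Mapping):
        labels = _read_labels(labels)
    return build_panel(sequences, labels)
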