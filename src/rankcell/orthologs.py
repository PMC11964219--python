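"""Human-mouse ortholog gene-identifier conversion.

Two homology tables are composed: stage 1 maps human Ensembl IDs through
gene symbols to mouse MGI IDs (HGNC-style), stage 2 maps MGI IDs to mouse
Ensembl IDs (MGI-style). Either stage can be one-to-many; a deterministic
one-to-one table is produced by two tie-break rules: for a human ID with
several (symbol, MGI) candidates, symbols are sorted alphabetically and the
last one's MGI is chosen; for an MGI ID with several mouse Ensembl IDs, the
final ID in the table's output order is chosen. Record order in the stage-2
table is therefore semantically load-bearing and preserved by the readers.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import RawDataset
from .errors import DataError

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix (``ENSMUSG...123.4`` -> no ``.4``)."""
    return _VERSION_RE.sub("", gene_id)


@dataclass
class HomologyRecords:
    """Raw two-stage homology records, file order preserved.

    ``stage1`` columns: human_ensembl_id, gene_symbol, mouse_mgi_id.
    ``stage2`` columns: mouse_mgi_id, mouse_ensembl_id.
    """

    stage1: pd.DataFrame
    stage2: pd.DataFrame

    def __post_init__(self):
        for df, cols in ((self.stage1, ["human_ensembl_id", "gene_symbol",
                                        "mouse_mgi_id"]),
                         (self.stage2, ["mouse_mgi_id", "mouse_ensembl_id"])):
            missing = set(cols) - set(df.columns)
            if missing:
                raise DataError(f"homology table missing columns {sorted(missing)}")
            for c in cols:
                vals = df[c].astype(str)
                if (vals.str.len() == 0).any() or vals.isin(["nan", "None"]).any():
                    raise DataError(f"empty identifiers in column {c!r}")
        if self.stage1.duplicated().any() or self.stage2.duplicated().any():
            raise DataError("fully duplicated homology records")

    @classmethod
    def from_tsv(cls, stage1_path, stage2_path) -> "HomologyRecords":
        return cls(stage1=pd.read_csv(stage1_path, sep="\t", dtype=str),
                   stage2=pd.read_csv(stage2_path, sep="\t", dtype=str))


@dataclass
class OrthologTable:
    """One-to-one human<->mouse Ensembl mapping with tie-break provenance."""

    forward: dict[str, str]  # human -> mouse
    provenance: pd.DataFrame  # per mapped human id: symbol, mgi, tie_break
    unmapped_human: list[str] = field(default_factory=list)
    unmapped_mouse: list[str] = field(default_factory=list)

    @property
    def reverse(self) -> dict[str, str]:
        return {m: h for h, m in self.forward.items()}

    def to_tsv(self, path) -> None:
        self.provenance.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OrthologTable":
        prov = pd.read_csv(path, sep="\t", dtype={"tie_break": bool}, keep_default_na=False)
        fwd = dict(zip(prov["human_ensembl_id"], prov["mouse_ensembl_id"]))
        return cls(forward=fwd, provenance=prov)


def resolve_one_to_one(records: HomologyRecords) -> OrthologTable:
    """Collapse one-to-many homology records into a one-to-one table.

    Tie-breaks: (1) per human ID, candidate symbols sorted alphabetically
    (case-insensitive, then case-sensitive, then file order) and the last
    record's MGI is chosen; (2) per MGI ID, the final mouse Ensembl ID in
    stage-2 output order is chosen. Residual collisions of two human IDs on
    one mouse Ensembl ID keep the lexicographically smallest human ID; the
    rest are unmapped. Provenance records every fired tie-break.
    """
    s1 = records.stage1.copy()
    s1["human_ensembl_id"] = s1["human_ensembl_id"].map(strip_version)
    s2 = records.stage2.copy()
    s2["mouse_ensembl_id"] = s2["mouse_ensembl_id"].map(strip_version)

    # stage 2: MGI -> final mouse Ensembl ID in output order
    mgi_to_ens: dict[str, str] = {}
    mgi_multiplicity: dict[str, int] = {}
    for _, row in s2.iterrows():
        mgi_to_ens[row["mouse_mgi_id"]] = row["mouse_ensembl_id"]
        mgi_multiplicity[row["mouse_mgi_id"]] = \
            mgi_multiplicity.get(row["mouse_mgi_id"], 0) + 1

    rows = []
    unmapped_human: list[str] = []
    for hid, grp in s1.groupby("human_ensembl_id", sort=True):
        grp = grp.reset_index(drop=True)
        order = sorted(
            range(len(grp)),
            key=lambda i: (grp["gene_symbol"][i].lower(), grp["gene_symbol"][i], i),
        )
        chosen = grp.iloc[order[-1]]
        tie1 = len(grp) > 1
        mgi = chosen["mouse_mgi_id"]
        if mgi not in mgi_to_ens:
            unmapped_human.append(hid)
            continue
        tie2 = mgi_multiplicity[mgi] > 1
        rows.append({
            "human_ensembl_id": hid,
            "chosen_symbol": chosen["gene_symbol"],
            "chosen_mgi_id": mgi,
            "mouse_ensembl_id": mgi_to_ens[mgi],
            "tie_break": bool(tie1 or tie2),
        })

    prov = pd.DataFrame(rows, columns=["human_ensembl_id", "chosen_symbol",
                                       "chosen_mgi_id", "mouse_ensembl_id",
                                       "tie_break"])
    # enforce injectivity of the composed mapping
    if len(prov):
        keep = prov.sort_values("human_ensembl_id") \
                   .drop_duplicates("mouse_ensembl_id", keep="first")
        dropped = sorted(set(prov["human_ensembl_id"]) - set(keep["human_ensembl_id"]))
        unmapped_human.extend(dropped)
        prov = keep.sort_values("human_ensembl_id").reset_index(drop=True)
    forward = dict(zip(prov["human_ensembl_id"], prov["mouse_ensembl_id"]))
    mapped_mouse = set(forward.values())
    unmapped_mouse = sorted(
        {e for e in s2["mouse_ensembl_id"]} - mapped_mouse)
    return OrthologTable(forward=forward, provenance=prov,
                         unmapped_human=sorted(unmapped_human),
                         unmapped_mouse=unmapped_mouse)


@dataclass
class ConversionReport:
    """Outcome of a gene-axis identifier conversion."""

    n_mapped: int
    n_dropped: int
    dropped_genes: list[str]
    direction: str


def convert_matrix(dataset: RawDataset, table: OrthologTable, direction: str
                   ) -> tuple[RawDataset, ConversionReport]:
    """Rename mapped genes, drop unmapped ones; counts are untouched.

    ``direction`` is ``"human-to-mouse"`` or ``"mouse-to-human"``.
    """
    if direction == "human-to-mouse":
        mapping = table.forward
    elif direction == "mouse-to-human":
        mapping = table.reverse
    else:
        raise DataError(f"unknown direction {direction!r}")
    src_ids = [strip_version(str(g)) for g in dataset.gene_ids]
    keep = [i for i, g in enumerate(src_ids) if g in mapping]
    new_ids = [mapping[src_ids[i]] for i in keep]
    if len(set(new_ids)) != len(new_ids):
        dupes = pd.Series(new_ids).value_counts()
        raise DataError(
            "one-to-one violation: duplicate target identifiers "
            f"{list(dupes[dupes > 1].index[:5])}")
    dropped = [src_ids[i] for i in range(len(src_ids)) if i not in set(keep)]
    out = RawDataset(
        counts=dataset.counts[keep, :].tocsr(),
        gene_ids=np.array(new_ids, dtype=object),
        mito_flags=dataset.mito_flags[keep],
        cell_meta=dataset.cell_meta.copy(),
    )
    report = ConversionReport(n_mapped=len(keep), n_dropped=len(dropped),
                              dropped_genes=dropped, direction=direction)
    return out, report
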