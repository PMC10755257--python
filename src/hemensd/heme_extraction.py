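"""mmCIF parsing and heme entry extraction.

Locates heme compounds (HEM, HEA, HEB, HEC, HEO) in macromolecular mmCIF
files, applies the primary-site selection rule (PDB model number 1; among
alternative locations keep '.', else 'A'), enforces the intactness rule
(all 25 Fe-porphyrin skeleton atoms present) and emits one ``HemeEntry``
per heme occurrence together with entry-level metadata.

Parsing goes through gemmi's CIF reader but operates on the raw
``_atom_site`` records rather than a built Structure, so the selection
rules are applied exactly as specified and are directly testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .exceptions import StructureParseError
from .reference_geometry import SKELETON_LABELS, element_of

logger = logging.getLogger(__name__)

#: Compound IDs recognized as hemes.
HEME_COMP_IDS = frozenset({"HEM", "HEA", "HEB", "HEC", "HEO"})


@dataclass(frozen=True)
class AtomRecord:
    """One selected atom site from an mmCIF ``_atom_site`` loop."""

    label: str           # atom name (label_atom_id)
    element: str
    xyz: tuple[float, float, float]
    model: int = 1
    altloc: str = "."
    entity_id: str = ""
    asym_id: str = ""
    chain_id: str = ""
    residue_index: int = 0
    comp_id: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array(self.xyz)


@dataclass
class EntryMetadata:
    """Header-level metadata; absent fields are explicit ``None``."""

    pdb_id: str | None = None
    resolution: float | None = None
    method: str | None = None
    deposition_date: str | None = None
    keywords: str | None = None
    function: str | None = None
    entity_descriptions: dict[str, str] = field(default_factory=dict)
    entity_ec: dict[str, str] = field(default_factory=dict)
    entity_organism: dict[str, str] = field(default_factory=dict)


@dataclass
class HemeEntry:
    """One heme occurrence with an intact 25-atom skeleton."""

    pdb_id: str
    asym_id: str
    chain_id: str
    residue_index: int
    comp_id: str
    coords: np.ndarray                       # (25, 3), canonical atom order
    sidechain: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: EntryMetadata | dict = field(default_factory=dict)

    @property
    def identity(self) -> tuple[str, str, int, str]:
        return (self.pdb_id, self.asym_id, self.residue_index, self.chain_id)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(element_of(lab) for lab in SKELETON_LABELS)


@dataclass
class ParsedStructure:
    """Primary-selected atom records plus metadata for one mmCIF file."""

    pdb_id: str
    atoms: list[AtomRecord]
    metadata: EntryMetadata

    def heme_residues(self) -> dict[tuple, list[AtomRecord]]:
        groups: dict[tuple, list[AtomRecord]] = {}
        for a in self.atoms:
            if a.comp_id in HEME_COMP_IDS:
                key = (a.asym_id, a.chain_id, a.residue_index, a.comp_id)
                groups.setdefault(key, []).append(a)
        return groups

    def atoms_excluding_residue(
        self, asym_id: str, chain_id: str, residue_index: int
    ) -> list[AtomRecord]:
        return [
            a for a in self.atoms
            if not (a.asym_id == asym_id and a.chain_id == chain_id
                    and a.residue_index == residue_index)
        ]


# --------------------------------------------------------------------------
# Selection rules
# --------------------------------------------------------------------------


def select_primary_sites(records: list[AtomRecord]) -> AtomRecord | None:
    """Pick the single record to keep for one atom identity.

    Only PDB model number 1 is used; among alternative-location indicators
    the blank '.' is kept when present, otherwise 'A'.  An atom present only
    with other altlocs is treated as missing (feeding the intactness skip).
    """
    model1 = [r for r in records if r.model == 1]
    for want in (".", "A"):
        for r in model1:
            if r.altloc == want:
                return r
    return None


# --------------------------------------------------------------------------
# mmCIF reading
# --------------------------------------------------------------------------

_ATOM_SITE_TAGS = [
    "label_atom_id", "label_comp_id", "Cartn_x", "Cartn_y", "Cartn_z",
    "?type_symbol", "?label_alt_id", "?label_asym_id", "?label_entity_id",
    "?auth_asym_id", "?auth_seq_id", "?label_seq_id", "?pdbx_PDB_model_num",
]


def _first_value(block: gemmi.cif.Block, *tags: str) -> str | None:
    for tag in tags:
        val = block.find_value(tag)
        if val is not None and val not in (".", "?"):
            return gemmi.cif.as_string(val)
    return None


def collect_entry_metadata(block: gemmi.cif.Block) -> EntryMetadata:
    """Header metadata with explicit nulls for absent categories.

    Resolution is taken from ``_refine.ls_d_res_high`` when present, then
    ``_reflns.d_resolution_high``; structures without either (e.g. NMR)
    report ``None``.
    """
    md = EntryMetadata()
    md.pdb_id = _first_value(block, "_entry.id") or block.name or None
    res = _first_value(block, "_refine.ls_d_res_high",
                       "_reflns.d_resolution_high")
    md.resolution = float(res) if res is not None else None
    md.method = _first_value(block, "_exptl.method")
    md.deposition_date = _first_value(
        block, "_pdbx_database_status.recvd_initial_deposition_date"
    )
    md.keywords = _first_value(block, "_struct_keywords.pdbx_keywords",
                               "_struct_keywords.text")
    md.function = assign_function(md.keywords)

    ent = block.find("_entity.", ["id", "?pdbx_description", "?pdbx_ec"])
    for row in ent:
        eid = gemmi.cif.as_string(row[0])
        if row.has(1) and row.str(1) not in ("", "?", "."):
            md.entity_descriptions[eid] = row.str(1)
        if row.has(2) and row.str(2) not in ("", "?", "."):
            md.entity_ec[eid] = row.str(2)
    for cat, tag in (("_entity_src_gen.", "pdbx_gene_src_scientific_name"),
                     ("_entity_src_nat.", "pdbx_organism_scientific")):
        table = block.find(cat, ["entity_id", tag])
        for row in table:
            eid = gemmi.cif.as_string(row[0])
            val = row.str(1)
            if val not in ("", "?", ".") and eid not in md.entity_organism:
                md.entity_organism[eid] = val
    return md


def read_mmcif(path: str | Path) -> ParsedStructure:
    """Parse an mmCIF file and apply the primary-site selection rule."""
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    table = block.find("_atom_site.", _ATOM_SITE_TAGS)
    if len(table) == 0:
        raise StructureParseError(f"{path} has no _atom_site records")

    raw: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for row in table:
        def opt(i: int, default: str = "") -> str:
            return row.str(i) if row.has(i) else default

        seq_str = opt(10) or opt(11)
        try:
            seq = int(seq_str) if seq_str not in ("", ".", "?") else 0
        except ValueError:
            seq = 0
        model_str = opt(12, "1")
        rec = AtomRecord(
            label=row.str(0),
            comp_id=row.str(1),
            xyz=(float(row.str(2)), float(row.str(3)), float(row.str(4))),
            element=opt(5) or "C",
            altloc=opt(6) or ".",
            asym_id=opt(7),
            entity_id=opt(8),
            chain_id=opt(9) or opt(7),
            residue_index=seq,
            model=int(model_str) if model_str not in ("", ".", "?") else 1,
        )
        key = (rec.asym_id, rec.chain_id, rec.residue_index, rec.comp_id,
               rec.label)
        if key not in raw:
            order.append(key)
        raw.setdefault(key, []).append(rec)

    atoms = []
    for key in order:
        chosen = select_primary_sites(raw[key])
        if chosen is not None:
            atoms.append(chosen)

    metadata = collect_entry_metadata(block)
    pdb_id = metadata.pdb_id or Path(path).stem
    return ParsedStructure(pdb_id=pdb_id, atoms=atoms, metadata=metadata)


# --------------------------------------------------------------------------
# Heme extraction
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SkipRecord:
    identity: tuple
    reason: str


def find_hemes(
    structure: ParsedStructure,
) -> tuple[list[HemeEntry], list[SkipRecord]]:
    """One entry per heme residue whose 25-atom skeleton is intact.

    Hemes missing any skeleton atom (after primary-site selection) are
    skipped and reported with their identity and reason.
    """
    entries: list[HemeEntry] = []
    skips: list[SkipRecord] = []
    for (asym, chain, seq, comp), recs in sorted(structure.heme_residues().items()):
        by_label = {r.label: r for r in recs}
        missing = [lab for lab in SKELETON_LABELS if lab not in by_label]
        identity = (structure.pdb_id, asym, seq, chain)
        if missing:
            reason = f"incomplete skeleton (missing {', '.join(missing[:5])})"
            skips.append(SkipRecord(identity, reason))
            logger.info("skipping heme %s: %s", identity, reason)
            continue
        coords = np.array([by_label[lab].coords for lab in SKELETON_LABELS])
        sidechain = {
            r.label: r.coords for r in recs if r.label not in SKELETON_LABELS
        }
        entries.append(
            HemeEntry(
                pdb_id=structure.pdb_id, asym_id=asym, chain_id=chain,
                residue_index=seq, comp_id=comp, coords=coords,
                sidechain=sidechain, metadata=structure.metadata,
            )
        )
    return entries, skips


def extract_hemes(path: str | Path) -> tuple[list[HemeEntry], list[SkipRecord]]:
    """Convenience: parse a file and extract its heme entries."""
    return find_hemes(read_mmcif(path))


# --------------------------------------------------------------------------
# Function mapping and CSV export
# --------------------------------------------------------------------------


def load_function_map(path: str | Path | None = None) -> dict[str, str]:
    """Keyword -> function table (shipped default or a user-edited copy)."""
    if path is None:
        text = (
            resources.files("hemensd") / "data" / "keyword_functions.tsv"
        ).read_text()
    else:
        text = Path(path).read_text()
    mapping = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("\t")
        if val:
            mapping[key.strip().upper()] = val.strip()
    return mapping


def assign_function(keywords: str | None,
                    mapping: dict[str, str] | None = None) -> str | None:
    """Map a pdbx_keywords string to a curated function label, or None."""
    if not keywords:
        return None
    if mapping is None:
        mapping = load_function_map()
    return mapping.get(keywords.strip().upper())


def entries_to_dataframe(entries: list[HemeEntry]) -> pd.DataFrame:
    """Flat entry table (identity + metadata) for CSV export."""
    rows = []
    for e in entries:
        md = e.metadata if isinstance(e.metadata, EntryMetadata) else EntryMetadata()
        rows.append({
            "pdb_id": e.pdb_id,
            "asym_id": e.asym_id,
            "chain_id": e.chain_id,
            "residue_index": e.residue_index,
            "comp_id": e.comp_id,
            "resolution": md.resolution,
            "method": md.method,
            "deposition_date": md.deposition_date,
            "keywords": md.keywords,
            "function": md.function,
        })
    return pd.DataFrame(
        rows,
        columns=["pdb_id", "asym_id", "chain_id", "residue_index", "comp_id",
                 "resolution", "method", "deposition_date", "keywords",
                 "function"],
    )
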