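"""Axial-ligand identification and per-ligand metadata normalization.

Axial ligands are the amino acids or other small molecules with any atom
within 3.1 A of the heme iron; the coordination distance of a candidate is
the minimum over its atoms, and when more than two candidates qualify only
the two nearest are kept (coordination number 0 to 2).  Organism strings are
truncated to their first two words and EC numbers to their first three class
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heme_extraction import AtomRecord, EntryMetadata, HemeEntry

#: Distance rule for coordination (Angstrom).
DEFAULT_CUTOFF = 3.1


@dataclass(frozen=True)
class AxialLigand:
    comp_id: str
    description: str | None
    chain_id: str
    residue_index: int
    coordinating_atom: str
    distance: float
    entity_id: str = ""
    organism: str | None = None
    ec: str | None = None
    uniprot: str | None = None
    cath: str | None = None


@dataclass(frozen=True)
class LigandAnnotation:
    heme_identity: tuple
    ligands: tuple[AxialLigand, ...]

    @property
    def coordination_number(self) -> int:
        return len(self.ligands)


def normalize_organism(raw: str | None) -> str | None:
    """First two whitespace-separated words of a scientific name."""
    if raw is None or not raw.strip():
        return None
    return " ".join(raw.split()[:2])


def truncate_ec(raw: str | None) -> str | None:
    """First three dot-separated class labels of an EC number."""
    if raw is None or not raw.strip():
        return None
    return ".".join(raw.strip().split(".")[:3])


def find_axial_ligands(
    heme: HemeEntry,
    neighbors: list[AtomRecord],
    cutoff: float = DEFAULT_CUTOFF,
    exclude_comp_ids: frozenset[str] | set[str] = frozenset(),
) -> LigandAnnotation:
    """Identify up to two axial ligands of a heme.

    ``neighbors`` are atom records of the surrounding structure; the heme's
    own atoms must already be excluded (see
    ``ParsedStructure.atoms_excluding_residue``).  Candidates are grouped by
    residue/molecule (chain + residue index); ties in distance are broken by
    chain ID then residue index.  Waters and ions participate by default;
    pass their comp IDs in ``exclude_comp_ids`` to ignore them.

    Zero candidates is a valid outcome (coordination number 0), as for a
    bare 4-coordinate heme.
    """
    fe = heme.coords[0]  # FE is the first canonical atom
    groups: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in neighbors:
        if a.comp_id in exclude_comp_ids:
            continue
        if (a.asym_id == heme.asym_id and a.chain_id == heme.chain_id
                and a.residue_index == heme.residue_index):
            continue  # the heme's own atoms never coordinate themselves
        groups.setdefault((a.chain_id, a.residue_index), []).append(a)

    md = heme.metadata if isinstance(heme.metadata, EntryMetadata) else None
    candidates: list[AxialLigand] = []
    for (chain, seq), atoms in groups.items():
        dists = [float(np.linalg.norm(a.coords - fe)) for a in atoms]
        i = int(np.argmin(dists))
        if dists[i] > cutoff:
            continue
        a = atoms[i]
        organism = ec = description = None
        if md is not None:
            description = md.entity_descriptions.get(a.entity_id)
            organism = normalize_organism(md.entity_organism.get(a.entity_id))
            ec = truncate_ec(md.entity_ec.get(a.entity_id))
        candidates.append(
            AxialLigand(
                comp_id=a.comp_id, description=description, chain_id=chain,
                residue_index=seq, coordinating_atom=a.label,
                distance=dists[i], entity_id=a.entity_id,
                organism=organism, ec=ec,
            )
        )

    candidates.sort(key=lambda lig: (lig.distance, lig.chain_id,
                                     lig.residue_index))
    return LigandAnnotation(
        heme_identity=heme.identity, ligands=tuple(candidates[:2])
    )
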