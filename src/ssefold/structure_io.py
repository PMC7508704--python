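"""Reading, sanitizing and writing RNA chains.

Deposited structures (PDB or mmCIF, both read natively through gemmi) are
split into single chains, and each chain is put through the library
ingestion filters:

1. residues with no recognizable parent base are dropped;
2. modified nucleotides are renamed to their parent base, keeping the atoms
   the parent shares;
3. residues with fewer than 9 observed heavy atoms are dropped;
4. remaining residues missing heavy atoms are completed by least-squares
   grafting of an idealized residue template onto the observed atoms;
5. residues are reindexed 1..n;
6. chains shorter than 6 nucleotides are rejected outright (they cannot
   form a smallest secondary element).

Every action is recorded in a sanitation report (tab-separated text).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np

from . import pair_annotation
from .chem import EXPECTED_HEAVY_ATOMS, MODIFIED_PARENT, residue_template
from .config import AnnotationParams, SanitationParams
from .errors import FormatError
from .geometry import superpose
from .model import AtomRecord, ResidueRecord, RnaChain

logger = logging.getLogger(__name__)

_WATER = {"HOH", "DOD", "WAT"}


def map_modified_residue(name: str) -> Optional[str]:
    """Parent standard base (A/C/G/U) for a residue code, or None.

    Standard codes map to themselves; modified nucleotides go through a
    curated parent-base lookup; anything else (amino acids, ligands, water,
    DNA) maps to None.
    """
    parent = MODIFIED_PARENT.get(name.strip().upper())
    if parent is None and name.strip().upper() not in _WATER:
        logger.debug("unknown residue code %r treated as non-RNA", name)
    return parent


def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name, hydrogens excluded."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        if atom.is_hydrogen():
            continue
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            chosen[atom.name] = atom
    return list(chosen.values())


def read_structure(path: str | Path, format: str = "auto") -> list[RnaChain]:
    """Read a structure file into unsanitized RNA chains.

    One chain is returned per author chain containing at least one
    nucleotide residue; protein/DNA-only/ligand/water chains are excluded.
    Multi-model files contribute their first model only.
    """
    path = Path(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise FormatError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    source_id = (st.name or path.stem).strip().upper() or path.stem.upper()
    chains: list[RnaChain] = []
    model = st[0]
    for chain in model:
        residues: list[ResidueRecord] = []
        n_nuc = 0
        for res in chain:
            if res.name.strip().upper() in _WATER:
                continue
            parent = map_modified_residue(res.name)
            atoms = [
                AtomRecord(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in _pick_altloc(res)
            ]
            if not atoms:
                continue
            if parent is not None:
                n_nuc += 1
            residues.append(ResidueRecord(res.name.strip(), parent, atoms, len(residues) + 1))
        if n_nuc >= 1:
            chains.append(RnaChain(source_id, chain.name, residues))
    return chains


def _complete_residue(res: ResidueRecord) -> list[str]:
    """Add missing heavy atoms by rigid grafting of the ideal template."""
    expected = EXPECTED_HEAVY_ATOMS[res.parent_base]
    present = res.atom_names()
    missing = sorted(expected - present)
    if not missing:
        return []
    template = residue_template(res.parent_base)
    shared = sorted(present & set(template))
    tmpl_xyz = np.array([template[n] for n in shared])
    obs_xyz = res.coords(shared)
    transform, _ = superpose(tmpl_xyz, obs_xyz)
    for name in missing:
        pos = transform.apply(template[name][None, :])[0]
        res.atoms.append(AtomRecord(name, name[0], pos))
    return missing


def sanitize_chain(
    chain: RnaChain, params: SanitationParams | None = None
) -> tuple[Optional[RnaChain], list[tuple[str, str]]]:
    """Apply the ingestion filters; returns (chain or None, report).

    Rejection of the whole chain (too short) is a reported outcome, not an
    error.  The operation is idempotent.
    """
    params = params or SanitationParams()
    report: list[tuple[str, str]] = []
    out = chain.copy()
    kept: list[ResidueRecord] = []
    for res in out.residues:
        tag = f"{chain.source_id}/{chain.chain_id}/{res.index}:{res.original_name}"
        if res.parent_base is None:
            report.append(("drop_non_rna", tag))
            continue
        if res.original_name != res.parent_base:
            expected = EXPECTED_HEAVY_ATOMS[res.parent_base]
            res.atoms = [a for a in res.atoms if a.name in expected]
            res.original_name = res.parent_base
            report.append(("rename_modified", tag))
        if len(res.atoms) < params.min_atoms_per_residue:
            report.append(("drop_few_atoms", f"{tag} ({len(res.atoms)} atoms)"))
            continue
        added = _complete_residue(res)
        if added:
            report.append(("complete_atoms", f"{tag} +{','.join(added)}"))
        kept.append(res)
    out.residues = kept
    out.reindex()
    if len(out) < params.min_chain_length:
        report.append(("reject_chain", f"{chain.source_id}/{chain.chain_id} ({len(out)} nt)"))
        return None, report
    return out, report


def format_report(report: Iterable[tuple[str, str]]) -> str:
    return "".join(f"{action}\t{what}\n" for action, what in report)


def dedupe_chains(
    chains: list[RnaChain], annotation: AnnotationParams | None = None
) -> list[RnaChain]:
    """Keep one representative among chains with identical sequence *and*
    identical derived secondary structure (first encountered wins)."""
    from .secondary_structure import to_dotbracket

    seen: set[tuple[str, str]] = set()
    kept: list[RnaChain] = []
    for chain in chains:
        if chain.secondary_structure is None:
            pair_annotation.derive_secondary_structure(chain, annotation)
        key = (chain.sequence, to_dotbracket(chain.secondary_structure))
        if key in seen:
            continue
        seen.add(key)
        kept.append(chain)
    return kept


def write_pdb(path: str | Path, chains: Iterable[RnaChain]) -> None:
    """Write chains as a (single-model) PDB file, residues named by base."""
    st = gemmi.Structure()
    st.name = "ssefold"
    model = gemmi.Model("1")
    for chain in chains:
        gchain = gemmi.Chain(chain.chain_id or "A")
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.parent_base or res.original_name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))
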