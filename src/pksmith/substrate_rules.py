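"""Rule-based module substrate maturation.

Each extension module loads an extender unit chosen by its AT domain and then
optionally processes the unit's carbonyl with the standard reductive ladder:

======================  ==================  =======================
active domains          oxidation state     beta-position group
======================  ==================  =======================
(none)                  ketone              C=O
KR                      hydroxyl            CH-OH
KR + DH                 enoyl               C=C (dehydrated)
KR + DH + ER            saturated           CH2
======================  ==================  =======================

The unit is a two-carbon fragment: the carbonyl carbon C1 (which becomes the
beta-position of the next condensation, or the free-acid carboxyl at the chain
terminus) and the alpha carbon C2 carrying the branch (H for mal, methyl for
mmal).  Inactive domains are skipped; a DH without KR or an ER without DH is a
rule violation and falls back to the deepest consistent state.  Stereochemistry
is not modelled.

Inactive-domain detection is a transparent, editable heuristic: a reductive
domain lacking its packaged catalytic-residue pattern (e.g. the KR
NADPH-binding motif) is flagged inactive.  Flags already set on the input are
never overridden.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .bgc_model import Domain, Module

OXIDATION_STATES = ("ketone", "hydroxyl", "enoyl", "saturated")


class SubstrateError(ValueError):
    pass


@dataclass(frozen=True)
class Monomer:
    label: str
    smiles: str
    carbonyl_atom_index: int
    alpha_atom_index: int


@dataclass
class MonomerLibrary:
    """Substrate label -> extender building block with marked attachment atoms."""

    monomers: dict[str, Monomer]

    def __getitem__(self, label: str) -> Monomer:
        try:
            return self.monomers[label]
        except KeyError:
            raise SubstrateError(f"substrate label {label!r} not in monomer library")

    def __contains__(self, label: str) -> bool:
        return label in self.monomers

    @classmethod
    def load(cls, path: str | Path | None = None) -> "MonomerLibrary":
        if path is None:
            path = str(resources.files("pksmith") / "data" / "monomer_library.json")
        with open(path) as fh:
            obj = json.load(fh)
        monomers = {}
        for label, entry in obj["monomers"].items():
            mol = Chem.MolFromSmiles(entry["smiles"])
            if mol is None:
                raise SubstrateError(f"monomer {label}: unparseable SMILES")
            for key in ("carbonyl_atom_index", "alpha_atom_index"):
                if entry[key] >= mol.GetNumAtoms():
                    raise SubstrateError(f"monomer {label}: {key} out of range")
            monomers[label] = Monomer(
                label=label,
                smiles=entry["smiles"],
                carbonyl_atom_index=entry["carbonyl_atom_index"],
                alpha_atom_index=entry["alpha_atom_index"],
            )
        return cls(monomers)


@dataclass
class ModuleSubstrate:
    """A module's mature two-carbon substructure.

    ``mol`` carries atom bookkeeping properties ``unitRole`` in {"carbonyl",
    "alpha"} used by the core assembler; ``smiles`` is the canonical
    standalone serialization (enoyl drawn intra-unit so the formula ladder
    ketone +H2 -> hydroxyl -H2O -> enoyl +H2 -> saturated holds per unit).
    """

    label: str
    oxidation_state: str
    mol: Chem.Mol
    smiles: str
    branch: str = ""

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)


def _state_from_domains(module: Module) -> str:
    kr = module.get("KR")
    dh = module.get("DH")
    er = module.get("ER")
    has = {
        "KR": kr is not None and kr.active,
        "DH": dh is not None and dh.active,
        "ER": er is not None and er.active,
    }
    if has["DH"] and not has["KR"]:
        warnings.warn("DH without active KR: falling back to ketone")
        return "ketone"
    if has["ER"] and not has["DH"]:
        if has["KR"]:
            warnings.warn("ER without active DH: falling back to hydroxyl")
            return "hydroxyl"
        warnings.warn("ER without active KR/DH: falling back to ketone")
        return "ketone"
    if has["ER"]:
        return "saturated"
    if has["DH"]:
        return "enoyl"
    if has["KR"]:
        return "hydroxyl"
    return "ketone"


def build_unit(monomer: Monomer, oxidation_state: str) -> ModuleSubstrate:
    """Construct the unit graph for a monomer at a given oxidation state."""
    if oxidation_state not in OXIDATION_STATES:
        raise SubstrateError(f"unknown oxidation state {oxidation_state!r}")
    mol = Chem.MolFromSmiles(monomer.smiles)
    rw = Chem.RWMol(mol)
    c1 = monomer.carbonyl_atom_index
    c2 = monomer.alpha_atom_index
    rw.GetAtomWithIdx(c1).SetProp("unitRole", "carbonyl")
    rw.GetAtomWithIdx(c2).SetProp("unitRole", "alpha")
    # locate the carbonyl oxygen (double-bonded O on C1)
    oxy = None
    for nb in rw.GetAtomWithIdx(c1).GetNeighbors():
        if nb.GetSymbol() == "O":
            oxy = nb.GetIdx()
    if oxy is None:
        raise SubstrateError(f"monomer {monomer.label}: no carbonyl oxygen on C1")
    if oxidation_state == "hydroxyl":
        rw.GetBondBetweenAtoms(c1, oxy).SetBondType(Chem.BondType.SINGLE)
    elif oxidation_state in ("enoyl", "saturated"):
        rw.RemoveAtom(oxy)
        if oxy < c1:
            c1 -= 1
        if oxy < c2:
            c2 -= 1
        if oxidation_state == "enoyl":
            rw.GetBondBetweenAtoms(c1, c2).SetBondType(Chem.BondType.DOUBLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return ModuleSubstrate(
        label=monomer.label,
        oxidation_state=oxidation_state,
        mol=out,
        smiles=Chem.MolToSmiles(out),
        branch="" if monomer.label == "mal" else monomer.label,
    )


def module_substrate(
    module: Module, at_label: str, library: MonomerLibrary | None = None
) -> ModuleSubstrate:
    """Mature substructure for a module given its AT substrate label.

    KR reduces the carbonyl to a hydroxyl, DH dehydrates the hydroxyl to an
    olefin, ER saturates the olefin; inactive-flagged domains are skipped.
    Pure: identical inputs give identical canonical SMILES.
    """
    if not module.is_extension:
        raise SubstrateError("module has no AT domain; not an extension module")
    if library is None:
        library = MonomerLibrary.load()
    return build_unit(library[at_label], _state_from_domains(module))


# ---------------------------------------------------------------------------
# Inactive-domain heuristic
# ---------------------------------------------------------------------------

def load_motif_table(path: str | Path | None = None) -> dict[str, str]:
    if path is None:
        path = str(resources.files("pksmith") / "data" / "catalytic_motifs.json")
    with open(path) as fh:
        return json.load(fh)["motifs"]


def detect_inactive_domains(
    module: Module, motif_table: dict[str, str] | None = None
) -> Module:
    """Flag reductive domains lacking their catalytic motif as inactive.

    Only applies to domains whose kind has a pattern in the table; pre-set
    ``active=False`` flags from the input are never overridden (a domain
    already marked inactive stays inactive even if the motif is present).
    """
    if motif_table is None:
        motif_table = load_motif_table()
    new_domains = []
    for d in module.domains:
        if not d.active:
            new_domains.append(d)
            continue
        pattern = motif_table.get(d.kind)
        if pattern is None:
            if d.kind in ("KR", "DH", "ER"):
                warnings.warn(f"no catalytic pattern for {d.kind}: left active")
            new_domains.append(d)
            continue
        if re.search(pattern, d.sequence) is None:
            new_domains.append(replace(d, active=False))
        else:
            new_domains.append(d)
    return Module(domains=new_domains, index=module.index)
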