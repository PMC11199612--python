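"""Core polyketide assembly and combinatorial tailoring.

``assemble_core`` chains ordered module substrates by Claisen condensation
(the alpha-carbon of each downstream unit bonds to the carbonyl carbon of the
upstream chain) and caps the chain as a free carboxylic acid.
``release_products`` emits the linear acid plus, when a thioesterase is
present, one macrolactone per eligible hydroxyl nucleophile.

Tailoring modifications are declarative rules: a substructure motif (SMARTS;
each rule also carries a valid-SMILES ``example`` embedding the motif, used
for validation) plus an ordered graph-edit script (add/remove atoms and
bonds, attach a fragment) addressed by motif-match atom indices.  Rules are
matched with RDKit substructure search (embeddings deduplicated to unique
atom sets) and applied with a valence-checked editor.  For a BGC with k core
structures and tailoring enzymes with m_1..m_n matched sites, each enzyme is
applied at most once at one chosen site or skipped, giving k x (m_1+1) x ...
x (m_n+1) raw candidate products, streamed lazily.

The packaged rule database (``data/tailoring_rules_synthetic.json``) is a
78-entry set curated for this package covering the standard polyketide
tailoring families (glycosylation with a small sugar library, O-/N-/C-
methylation, hydroxylation, epoxidation, acyl transfer, halogenation,
phosphorylation/sulfation, redox and cyclization reactions).  It is a
synthetic stand-in for a literature-transcribed database: the reaction
chemistry per family is standard, but site preferences of real enzymes are
not modelled.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .substrate_rules import ModuleSubstrate

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATE_CAP = 1_000_000
MIN_LACTONE_RING = 5


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Core assembly
# ---------------------------------------------------------------------------

def _role_atoms(mol: Chem.Mol) -> tuple[int, int]:
    c1 = c2 = None
    for atom in mol.GetAtoms():
        if atom.HasProp("unitRole"):
            role = atom.GetProp("unitRole")
            if role == "carbonyl":
                c1 = atom.GetIdx()
            elif role == "alpha":
                c2 = atom.GetIdx()
    if c1 is None or c2 is None:
        raise StructureError("module substrate lacks attachment-atom annotations")
    return c1, c2


def assemble_core(
    substrates: Sequence[ModuleSubstrate], starter_unknown: bool = False
) -> Chem.Mol:
    """Chain module substrates into the linear core (free-acid form).

    Substrates are in assembly order, first module first.  Consecutive units
    are joined by a bond from the downstream alpha-carbon to the upstream
    carbonyl carbon; an upstream unit in the enoyl state places its olefin on
    that condensation bond (alpha,beta-unsaturation).  The final unit's
    carbonyl becomes the carboxyl of the released acid; a reduced state on
    the final unit has no beta-position inside the chain and is ignored with
    a warning.  Atom properties record the monomer trace (``module`` index,
    ``unitRole``); with ``starter_unknown`` the first unit's alpha carbon is
    marked as the attachment point for an unresolved starter acyl group
    (handled downstream by variable spectral search).
    """
    if not substrates:
        raise StructureError("no substrates to assemble")
    combined = None
    c1_prev = None
    unit_atoms: list[tuple[int, int]] = []
    for i, sub in enumerate(substrates):
        unit = Chem.Mol(sub.mol)
        for atom in unit.GetAtoms():
            atom.SetIntProp("module", i)
        offset = combined.GetNumAtoms() if combined is not None else 0
        combined = unit if combined is None else Chem.CombineMols(combined, unit)
        uc1, uc2 = _role_atoms(sub.mol)
        unit_atoms.append((uc1 + offset, uc2 + offset))
    rw = Chem.RWMol(combined)
    for i in range(1, len(substrates)):
        c1_up, _ = unit_atoms[i - 1]
        _, alpha_down = unit_atoms[i]
        if substrates[i - 1].oxidation_state == "enoyl":
            # shift the standalone intra-unit olefin onto the condensation bond
            uc1, uc2 = unit_atoms[i - 1]
            rw.GetBondBetweenAtoms(uc1, uc2).SetBondType(Chem.BondType.SINGLE)
            rw.AddBond(c1_up, alpha_down, Chem.BondType.DOUBLE)
        else:
            rw.AddBond(c1_up, alpha_down, Chem.BondType.SINGLE)
    # terminal carboxyl on the last unit's carbonyl carbon
    last_c1, last_c2 = unit_atoms[-1]
    last_state = substrates[-1].oxidation_state
    if last_state != "ketone":
        warnings.warn(
            f"terminal unit in state {last_state!r}: its beta-position lies "
            "outside the chain; carbonyl normalized to the free-acid carboxyl"
        )
    c1_atom = rw.GetAtomWithIdx(last_c1)
    bond = rw.GetBondBetweenAtoms(last_c1, last_c2)
    if bond.GetBondType() == Chem.BondType.DOUBLE:  # terminal enoyl
        bond.SetBondType(Chem.BondType.SINGLE)
    has_dbl_o = has_single_o = False
    for nb in c1_atom.GetNeighbors():
        if nb.GetSymbol() == "O":
            bt = rw.GetBondBetweenAtoms(last_c1, nb.GetIdx()).GetBondType()
            if bt == Chem.BondType.DOUBLE:
                has_dbl_o = True
            else:
                has_single_o = True
    if not has_dbl_o:
        o = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(last_c1, o, Chem.BondType.DOUBLE)
    if not has_single_o:
        o = rw.AddAtom(Chem.Atom(8))
        rw.AddBond(last_c1, o, Chem.BondType.SINGLE)
    rw.GetAtomWithIdx(last_c1).SetProp("acidC", "1")
    if starter_unknown:
        _, first_alpha = unit_atoms[0]
        rw.GetAtomWithIdx(first_alpha).SetProp("attachment", "1")
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def monomer_trace(mol: Chem.Mol) -> dict[int, int]:
    """Atom index -> module index for atoms contributed by extender units."""
    return {
        a.GetIdx(): a.GetIntProp("module")
        for a in mol.GetAtoms()
        if a.HasProp("module")
    }


@dataclass
class CoreStructure:
    """A released core: canonical SMILES plus provenance annotations."""

    mol: Chem.Mol
    smiles: str
    cyclization: str  # "linear" or "macrolactone@<atom>"
    pathway_rank: int = 0

    @property
    def monoisotopic_mass(self) -> float:
        return Descriptors.ExactMolWt(self.mol)

    @property
    def formula(self) -> str:
        return rdMolDescriptors.CalcMolFormula(self.mol)


def _acid_atoms(mol: Chem.Mol) -> tuple[int, int] | None:
    """(carboxyl carbon, hydroxyl oxygen) of the terminal acid, if present."""
    for atom in mol.GetAtoms():
        if atom.HasProp("acidC"):
            for nb in atom.GetNeighbors():
                if (
                    nb.GetSymbol() == "O"
                    and nb.GetTotalNumHs() >= 1
                    and mol.GetBondBetweenAtoms(atom.GetIdx(), nb.GetIdx())
                    .GetBondType()
                    == Chem.BondType.SINGLE
                ):
                    return atom.GetIdx(), nb.GetIdx()
    return None


def release_products(
    chain: Chem.Mol, te_present: bool, min_ring: int = MIN_LACTONE_RING,
    pathway_rank: int = 0,
) -> list[CoreStructure]:
    """Linear free acid plus TE-mediated macrolactones.

    With a thioesterase present, every hydroxyl oxygen whose ester ring would
    contain at least ``min_ring`` atoms yields one macrolactone (ester bond
    from the acid carbonyl to that oxygen, water removed).
    """
    cores = [
        CoreStructure(
            mol=Chem.Mol(chain),
            smiles=Chem.MolToSmiles(chain),
            cyclization="linear",
            pathway_rank=pathway_rank,
        )
    ]
    if not te_present:
        return cores
    acid = _acid_atoms(chain)
    if acid is None:
        return cores
    acid_c, acid_oh = acid
    dmat = Chem.GetDistanceMatrix(Chem.Mol(chain))
    for atom in chain.GetAtoms():
        if atom.GetIdx() == acid_oh or atom.GetSymbol() != "O":
            continue
        if atom.GetDegree() != 1 or atom.GetTotalNumHs() < 1:
            continue
        bond = chain.GetBondBetweenAtoms(
            atom.GetIdx(), atom.GetNeighbors()[0].GetIdx()
        )
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        ring_size = int(dmat[acid_c, atom.GetIdx()]) + 1
        if ring_size < min_ring:
            continue
        # close the ester ring first, then drop the acid hydroxyl (removal
        # reindexes atoms, so the bond is added while indices are stable)
        nuc = atom.GetIdx()
        rw = Chem.RWMol(chain)
        rw.AddBond(nuc, acid_c, Chem.BondType.SINGLE)
        rw.RemoveAtom(acid_oh)
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # pragma: no cover - defensive
            continue
        cores.append(
            CoreStructure(
                mol=mol,
                smiles=Chem.MolToSmiles(mol),
                cyclization=f"macrolactone@{nuc}",
                pathway_rank=pathway_rank,
            )
        )
    return cores


# ---------------------------------------------------------------------------
# Modification rules
# ---------------------------------------------------------------------------

@dataclass
class ModificationRule:
    enzyme_tag: str
    motif: str
    edits: list[dict]
    citation: str = ""
    example: str | None = None
    formula_delta: dict[str, int] = field(default_factory=dict)
    _pattern: Chem.Mol | None = field(default=None, repr=False)

    @property
    def pattern(self) -> Chem.Mol:
        if self._pattern is None:
            pat = Chem.MolFromSmarts(self.motif)
            if pat is None:
                raise StructureError(
                    f"rule {self.enzyme_tag}: invalid motif {self.motif!r}"
                )
            object.__setattr__(self, "_pattern", pat)
        return self._pattern


def match_motif(core: Chem.Mol, rule: ModificationRule) -> list[tuple[int, ...]]:
    """All embeddings of the rule motif, one per unique matched atom set.

    Automorphic re-mappings of the same atoms are collapsed; matches are
    returned in deterministic order by sorted atom indices.
    """
    matches = core.GetSubstructMatches(rule.pattern, uniquify=True)
    return sorted(matches, key=lambda m: tuple(sorted(m)))


_BOND_ORDERS = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                3: Chem.BondType.TRIPLE}

_UID = "editUid"


def _resolve(rw: Chem.RWMol, uid_of: dict, addr) -> int:
    """Translate an edit address (motif index or 'n<j>') to a current index."""
    uid = uid_of[addr]
    for atom in rw.GetAtoms():
        if atom.HasProp(_UID) and atom.GetIntProp(_UID) == uid:
            return atom.GetIdx()
    raise StructureError(f"edit address {addr!r}: atom was removed")


def apply_rule(
    core: Chem.Mol, rule: ModificationRule, match: tuple[int, ...]
) -> Chem.Mol:
    """Execute the rule's graph-edit script against one motif embedding.

    Atoms are addressed by motif-match index (int) or ``"n<j>"`` for the
    j-th atom introduced by the script.  The product is valence-checked and
    canonicalized; an edit yielding invalid chemistry raises, naming the step.
    """
    rw = Chem.RWMol(core)
    next_uid = itertools.count()
    uid_of: dict = {}
    for atom in rw.GetAtoms():
        atom.SetIntProp(_UID, next(next_uid))
    for mi, atom_idx in enumerate(match):
        uid_of[mi] = rw.GetAtomWithIdx(atom_idx).GetIntProp(_UID)
    n_new = 0
    for step, edit in enumerate(rule.edits):
        op = edit["op"]
        try:
            if op == "add_atom":
                atom = Chem.Atom(edit["element"])
                if edit.get("charge"):
                    atom.SetFormalCharge(edit["charge"])
                uid = next(next_uid)
                atom.SetIntProp(_UID, uid)
                rw.AddAtom(atom)
                uid_of[f"n{n_new}"] = uid
                n_new += 1
            elif op == "remove_atom":
                rw.RemoveAtom(_resolve(rw, uid_of, edit["atom"]))
            elif op == "add_bond":
                a, b = _resolve(rw, uid_of, edit["a"]), _resolve(rw, uid_of, edit["b"])
                rw.AddBond(a, b, _BOND_ORDERS[edit.get("order", 1)])
            elif op == "remove_bond":
                a, b = _resolve(rw, uid_of, edit["a"]), _resolve(rw, uid_of, edit["b"])
                rw.RemoveBond(a, b)
            elif op == "set_bond":
                a, b = _resolve(rw, uid_of, edit["a"]), _resolve(rw, uid_of, edit["b"])
                bond = rw.GetBondBetweenAtoms(a, b)
                if bond is None:
                    raise StructureError("no bond to modify")
                bond.SetBondType(_BOND_ORDERS[edit["order"]])
            elif op == "set_charge":
                rw.GetAtomWithIdx(
                    _resolve(rw, uid_of, edit["atom"])
                ).SetFormalCharge(edit["charge"])
            elif op == "attach":
                frag = Chem.MolFromSmiles(edit["smiles"])
                if frag is None:
                    raise StructureError(f"bad fragment {edit['smiles']!r}")
                at = _resolve(rw, uid_of, edit["at"])
                base = rw.GetNumAtoms()
                for fa in frag.GetAtoms():
                    uid = next(next_uid)
                    fa.SetIntProp(_UID, uid)
                combined = Chem.RWMol(Chem.CombineMols(rw.GetMol(), frag))
                combined.AddBond(
                    at, base + edit.get("via", 0),
                    _BOND_ORDERS[edit.get("order", 1)],
                )
                rw = combined
            else:
                raise StructureError(f"unknown op {op!r}")
        except StructureError as exc:
            raise StructureError(
                f"rule {rule.enzyme_tag}, step {step} ({op}): {exc}"
            ) from exc
        except Exception as exc:  # RDKit editor errors (self-bond, ...)
            raise StructureError(
                f"rule {rule.enzyme_tag}, step {step} ({op}): {exc}"
            ) from exc
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise StructureError(
            f"rule {rule.enzyme_tag}: product fails valence check ({exc})"
        ) from exc
    return mol


# ---------------------------------------------------------------------------
# Rule database
# ---------------------------------------------------------------------------

@dataclass
class RuleDatabase:
    rules: dict[str, ModificationRule]

    def __len__(self) -> int:
        return len(self.rules)

    def __getitem__(self, tag: str) -> ModificationRule:
        return self.rules[tag]

    def __contains__(self, tag: str) -> bool:
        return tag in self.rules


def validate_rule(rule: ModificationRule) -> None:
    """Motif must parse; the edit script applied to the rule's own example
    (a molecule embedding the motif) must yield a valid molecule."""
    _ = rule.pattern
    example_smiles = rule.example or rule.motif
    example = Chem.MolFromSmiles(example_smiles)
    if example is None:
        raise StructureError(
            f"rule {rule.enzyme_tag}: example {example_smiles!r} is not valid SMILES"
        )
    matches = match_motif(example, rule)
    if not matches:
        raise StructureError(
            f"rule {rule.enzyme_tag}: motif does not match its own example"
        )
    apply_rule(example, rule, matches[0])


def load_modification_db(path: str | Path | None = None) -> RuleDatabase:
    """Load and validate a rule database; default is the packaged 78-rule set."""
    if path is None:
        path = str(
            resources.files("pksmith") / "data" / "tailoring_rules_synthetic.json"
        )
    with open(path) as fh:
        obj = json.load(fh)
    entries = obj["rules"] if isinstance(obj, dict) else obj
    rules: dict[str, ModificationRule] = {}
    seen: dict[tuple[str, str], str] = {}
    failures = []
    for entry in entries:
        rule = ModificationRule(
            enzyme_tag=entry["enzyme_tag"],
            motif=entry["motif"],
            edits=entry["edits"],
            citation=entry.get("citation", ""),
            example=entry.get("example"),
            formula_delta=entry.get("formula_delta", {}),
        )
        try:
            validate_rule(rule)
        except StructureError as exc:
            failures.append(str(exc))
            continue
        key = (rule.motif, json.dumps(rule.edits, sort_keys=True))
        if key in seen:
            warnings.warn(
                f"rules {seen[key]!r} and {rule.enzyme_tag!r} share (motif, edits); "
                "both kept"
            )
        seen[key] = rule.enzyme_tag
        if rule.enzyme_tag in rules:
            raise StructureError(f"duplicate enzyme tag {rule.enzyme_tag!r}")
        rules[rule.enzyme_tag] = rule
    if failures:
        raise StructureError(
            "rule database failed validation:\n" + "\n".join(failures)
        )
    return RuleDatabase(rules)


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

@dataclass
class CandidateCompound:
    mol: Chem.Mol
    smiles: str
    applied: list[tuple[str, int]]  # (enzyme_tag, site index)
    monoisotopic_mass: float
    core: CoreStructure


@dataclass
class EnumerationReport:
    k: int
    site_counts: list[dict[str, int]]  # per core: enzyme tag -> m_i
    raw_count: int
    deduplicated_count: int = 0
    emitted: int = 0
    truncated: bool = False


def enumerate_candidates(
    cores: Sequence[CoreStructure],
    enzymes: Sequence[str],
    db: RuleDatabase,
    cap: int = DEFAULT_CANDIDATE_CAP,
) -> tuple[Iterator[CandidateCompound], EnumerationReport]:
    """Lazily enumerate mature candidates over all modification combinations.

    Per enzyme with m matched sites on a core the choice set is {skip,
    apply-at-site-1, ..., apply-at-site-m}; the Cartesian product over
    enzymes, over all cores, yields the raw k x prod(m_i + 1) products.
    The report's ``raw_count`` is computed up front from the closed form;
    ``deduplicated_count`` (unique canonical SMILES) and ``emitted`` are
    finalized once the stream is exhausted.  The stream truncates at ``cap``
    with a logged notice; combinations whose edits collide chemically are
    dropped with a log entry (they still count as raw).
    """
    if cap < 1:
        raise StructureError("cap must be >= 1")
    usable = []
    for tag in enzymes:
        if tag in db:
            usable.append(tag)
        else:
            warnings.warn(f"tailoring tag {tag!r} not in rule database; skipped")
    per_core_matches: list[dict[str, list[tuple[int, ...]]]] = []
    site_counts: list[dict[str, int]] = []
    raw = 0
    for core in cores:
        matches = {tag: match_motif(core.mol, db[tag]) for tag in usable}
        per_core_matches.append(matches)
        counts = {tag: len(m) for tag, m in matches.items()}
        site_counts.append(counts)
        prod = 1
        for m in counts.values():
            prod *= m + 1
        raw += prod
    report = EnumerationReport(
        k=len(cores), site_counts=site_counts, raw_count=raw
    )

    def stream() -> Iterator[CandidateCompound]:
        seen: set[str] = set()
        for core, matches in zip(cores, per_core_matches):
            choice_sets = [
                [None] + list(range(len(matches[tag]))) for tag in usable
            ]
            for combo in itertools.product(*choice_sets):
                if report.emitted >= cap:
                    logger.info("candidate stream truncated at cap=%d", cap)
                    report.truncated = True
                    return
                mol = Chem.Mol(core.mol)
                applied: list[tuple[str, int]] = []
                ok = True
                for tag, site in zip(usable, combo):
                    if site is None:
                        continue
                    rule = db[tag]
                    # re-locate the site on the current (possibly edited) mol
                    cur = match_motif(mol, rule)
                    if site >= len(cur):
                        logger.debug(
                            "combination %s on core dropped: site %d for %s "
                            "no longer present", combo, site, tag,
                        )
                        ok = False
                        break
                    try:
                        mol = apply_rule(mol, rule, cur[site])
                    except StructureError as exc:
                        logger.debug("combination dropped: %s", exc)
                        ok = False
                        break
                    applied.append((tag, site))
                if not ok:
                    continue
                smiles = Chem.MolToSmiles(mol)
                report.emitted += 1
                if smiles not in seen:
                    seen.add(smiles)
                    report.deduplicated_count = len(seen)
                yield CandidateCompound(
                    mol=mol,
                    smiles=smiles,
                    applied=applied,
                    monoisotopic_mass=Descriptors.ExactMolWt(mol),
                    core=core,
                )

    return stream(), report
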