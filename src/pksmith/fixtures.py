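"""Deterministic synthetic fixtures with planted ground truth.

Every pipeline stage is testable without downloads: ``make_bgc`` emits a BGC
whose AT signatures carry label-determining residues, whose cognate gene
junctions share complementary 12-residue docking motifs (high bit-scores for
the planted assembly order), and whose reductive domains carry or lack their
catalytic motifs as configured.  ``make_at_training`` and
``make_docking_training`` emit separable-by-construction training sets drawn
from the same planted signal families.  ``make_spectrum`` builds a synthetic
tandem spectrum from a molecule's own depth-2 fragments with configurable
peak dropout, m/z jitter, and uniform decoy peaks.

Sequences are random apart from the planted signals; no biological realism
beyond that is attempted.  All randomness flows through one seeded generator,
so identical specs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from rdkit.Chem import Descriptors

from .at_specificity import SignatureProfile, load_reference
from .bgc_model import BGC, Domain, Gene, Module
from .spectral_search import PROTON_MASS, Spectrum, fragment

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: label-determining signature positions and per-label residues
PLANTED_POSITIONS = (3, 11, 19)
LABEL_RESIDUES = {"mal": "M", "mmal": "W", "emal": "E", "mxmal": "Q"}

#: docking connector families: (tail 12-mer, head 12-mer) pairs
_CONNECTOR_FAMILIES = 12

#: catalytic motifs embedded in active reductive domains (match the packaged
#: patterns in data/catalytic_motifs.json)
ACTIVE_MOTIFS = {"KR": "GSGKIG", "DH": "HAAAGIIIIP", "ER": "GGVG"}


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 4
    modules_per_gene: int = 2
    #: substrate label per module, in planted assembly order (cycled)
    labels: tuple[str, ...] = ("mal", "mmal")
    #: reductive domains per module, in planted order (cycled); each entry is
    #: a tuple drawn from {"KR","DH","ER"}
    reductive: tuple[tuple[str, ...], ...] = ((), ("KR",))
    #: planted assembly order as a permutation of 0..n_genes-1 applied to the
    #: genomic order; None = colinear
    planted_order: tuple[int, ...] | None = None
    #: tailoring enzyme tags present on the BGC
    enzymes: tuple[str, ...] = ()
    with_te: bool = False
    with_starter_module: bool = False
    # spectrum noise model
    peak_dropout: float = 0.0
    decoy_peaks: int = 0
    mz_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_dropout <= 1.0:
            raise FixtureError("peak_dropout must be in [0, 1]")
        if self.planted_order is not None:
            if sorted(self.planted_order) != list(range(self.n_genes)):
                raise FixtureError(
                    "planted_order must be a permutation of gene positions"
                )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, 20, length))


def make_signature(label: str, rng: np.random.Generator) -> SignatureProfile:
    """A signature whose planted positions carry the label's residue."""
    residues = list(_random_protein(rng, 24))
    for p in PLANTED_POSITIONS:
        residues[p] = LABEL_RESIDUES[label]
    return SignatureProfile("".join(residues), source_id=label)


def _at_domain_sequence(sig: SignatureProfile, rng: np.random.Generator) -> str:
    """Reference sequence with the signature planted at the marked columns
    and sparse random substitutions elsewhere (so queries differ from the
    reference but still align cleanly)."""
    ref = load_reference()
    seq = list(ref.sequence)
    marked = set(ref.columns)
    for i in range(len(seq)):
        if i not in marked and rng.random() < 0.05:
            seq[i] = _AA[rng.integers(0, 20)]
    for col, res in zip(ref.columns, sig.residues):
        seq[col] = res
    return "".join(seq)


def _connector(family: int, _rng=None) -> tuple[str, str]:
    """Deterministic (tail motif, head motif) 12-mers for a connector class."""
    rng = np.random.default_rng((9917, family))
    return _random_protein(rng, 12), _random_protein(rng, 12)


def _domain_seq(kind: str, active: bool, rng: np.random.Generator) -> str:
    body = _random_protein(rng, 60)
    if kind in ACTIVE_MOTIFS and active:
        motif = ACTIVE_MOTIFS[kind]
        pos = int(rng.integers(0, 60 - len(motif)))
        body = body[:pos] + motif + body[pos + len(motif):]
    elif kind in ACTIVE_MOTIFS:
        # ablate any accidental motif occurrence by construction: alanine run
        body = "A" * 60
    return body


def make_bgc(spec: FixtureSpec) -> tuple[BGC, dict]:
    """Synthetic BGC plus its ground-truth record.

    Genes are emitted in genomic order; the planted assembly order is the
    configured permutation of that order.  Consecutive genes in the planted
    order share a connector family: the upstream gene's tail and the
    downstream gene's head carry that family's complementary 12-mers.
    """
    rng = np.random.default_rng(spec.seed)
    order = (
        list(spec.planted_order)
        if spec.planted_order is not None
        else list(range(spec.n_genes))
    )
    # junction j sits between planted positions j and j+1; families are
    # distinct so no two junctions are interchangeable, and the pathway
    # terminals carry their own (never-pairing) families so every docking
    # region looks like the training distribution
    if spec.n_genes > _CONNECTOR_FAMILIES - 1:
        raise FixtureError(
            f"at most {_CONNECTOR_FAMILIES - 1} genes supported"
        )
    fam_choice = rng.choice(_CONNECTOR_FAMILIES - 2, size=spec.n_genes - 1,
                            replace=False)
    junction_family = {j: int(f) for j, f in enumerate(fam_choice)}
    head_terminal_family = _CONNECTOR_FAMILIES - 2
    tail_terminal_family = _CONNECTOR_FAMILIES - 1
    pos_in_order = {gpos: i for i, gpos in enumerate(order)}

    labels: list[str] = []
    genes: list[Gene] = []
    truth_modules: list[dict] = []
    mod_counter = 0
    genome_cursor = int(rng.integers(10_000, 20_000))
    for gpos in range(spec.n_genes):
        oi = pos_in_order[gpos]  # position in planted order
        head = _random_protein(rng, 100)
        tail = _random_protein(rng, 50)
        if oi > 0:
            _t, h = _connector(junction_family[oi - 1])
            head = h + head[12:]
        else:
            _t, h = _connector(head_terminal_family)
            head = h + head[12:]
        if oi < spec.n_genes - 1:
            t, _h = _connector(junction_family[oi])
            tail = tail[:-12] + t
        else:
            t, _h = _connector(tail_terminal_family)
            tail = tail[:-12] + t
        protein_parts = [head]
        modules: list[Module] = []
        offset = len(head)
        for mi in range(spec.modules_per_gene):
            domains: list[Domain] = []
            seqs: list[str] = []

            def put(kind: str, seq: str, active: bool = True) -> None:
                nonlocal offset
                domains.append(
                    Domain(kind=kind, sequence=seq, active=active,
                           coords=(offset, offset + len(seq)))
                )
                seqs.append(seq)
                offset += len(seq)

            is_first_module = gpos == order[0] and mi == 0
            if not (spec.with_starter_module and is_first_module):
                put("KS", _random_protein(rng, 80))
            label = spec.labels[mod_counter % len(spec.labels)]
            sig = make_signature(label, rng)
            if not (spec.with_starter_module and is_first_module):
                put("AT", _at_domain_sequence(sig, rng))
                labels.append(label)
                truth_modules.append(
                    {"gene_pos": gpos, "module": mi, "label": label,
                     "signature": sig.residues}
                )
            red = spec.reductive[mod_counter % len(spec.reductive)]
            for kind in ("KR", "DH", "ER"):
                if kind in red:
                    put(kind, _domain_seq(kind, True, rng))
            put("ACP", _random_protein(rng, 60))
            if (
                spec.with_te
                and gpos == order[-1]
                and mi == spec.modules_per_gene - 1
            ):
                put("TE", _random_protein(rng, 70))
            modules.append(Module(domains=domains, index=mi))
            protein_parts.extend(seqs)
            mod_counter += 1
        protein_parts.append(tail)
        protein = "".join(protein_parts)
        # re-anchor domain coords: they were laid out after the head already
        length_bp = 3 * len(protein)
        genes.append(
            Gene(
                id=f"g{gpos}",
                protein=protein,
                modules=modules,
                genomic_rank=gpos,
                strand="+",
                location=(genome_cursor, genome_cursor + length_bp),
            )
        )
        genome_cursor += length_bp + int(rng.integers(200, 2_000))
    tailoring = [
        Domain(kind=tag, sequence=_random_protein(rng, 120))
        for tag in spec.enzymes
    ]
    bgc = BGC(
        genes=genes,
        tailoring_enzymes=tailoring,
        source={"fixture_seed": spec.seed},
    )
    truth = {
        "planted_order": [f"g{p}" for p in order],
        "modules": truth_modules,
        "junction_families": junction_family,
        "enzymes": list(spec.enzymes),
    }
    return bgc, truth


# ---------------------------------------------------------------------------
# Training sets
# ---------------------------------------------------------------------------

def make_at_training(
    labels: tuple[str, ...] = ("mal", "mmal"),
    n_per_label: int = 30,
    seed: int = 0,
) -> list[tuple[SignatureProfile, str]]:
    """Separable signature training set (planted label-determining residues)."""
    rng = np.random.default_rng((seed, 101))
    out = []
    for label in labels:
        for _ in range(n_per_label):
            out.append((make_signature(label, rng), label))
    return out


from .assembly_order import DockingPair  # noqa: E402  (cycle-free)


def make_docking_training(
    per_family: int = 4,
    seed: int = 0,
) -> list[DockingPair]:
    """Labelled docking pairs from the fixture connector families.

    A positive pair's tail and head carry the same family's motifs; a
    negative pair mixes two different families.  Every family contributes
    ``per_family`` positives and ``per_family`` negatives, so coverage is
    deterministic and the classes are balanced by construction.  The default
    of 4 is the minimum adequately-powered size for the downstream
    nearest-neighbor features: with n = 3 neighbors per class and
    leave-self-out training, a positive query still finds 3 same-family
    interacting neighbors.
    """
    rng = np.random.default_rng((seed, 202))
    pairs: list[DockingPair] = []
    i = 0
    for fam in range(_CONNECTOR_FAMILIES):
        t, h = _connector(fam)
        for _rep in range(per_family):
            tail = _random_protein(rng, 38) + t
            head = h + _random_protein(rng, 88)
            pairs.append(DockingPair(tail_seq=tail, head_seq=head,
                                     label=True, id=f"pos{i}"))
            i += 1
    i = 0
    for fam in range(_CONNECTOR_FAMILIES):
        t, _ = _connector(fam)
        for rep in range(per_family):
            other = (fam + 1 + rep) % _CONNECTOR_FAMILIES
            _, h = _connector(other)
            tail = _random_protein(rng, 38) + t
            head = h + _random_protein(rng, 88)
            pairs.append(DockingPair(tail_seq=tail, head_seq=head,
                                     label=False, id=f"neg{i}"))
            i += 1
    return pairs


# ---------------------------------------------------------------------------
# Synthetic spectra
# ---------------------------------------------------------------------------

def make_spectrum(
    molecule, spec: FixtureSpec, identifier: str = "synthetic"
) -> Spectrum:
    """Synthetic [M+H]+ spectrum from the molecule's own depth-2 fragments.

    Peaks are thinned by ``peak_dropout``, jittered with Gaussian sd
    ``mz_jitter_sd``, and augmented with ``decoy_peaks`` uniform random
    peaks; the precursor is the exact [M+H]+.  Deterministic per spec seed.
    """
    rng = np.random.default_rng((spec.seed, 303))
    frags = fragment(molecule, depth=2)
    mz = frags.masses + PROTON_MASS
    if spec.peak_dropout > 0:
        keep = rng.random(mz.size) >= spec.peak_dropout
        mz = mz[keep]
    if spec.mz_jitter_sd > 0:
        mz = mz + rng.normal(0.0, spec.mz_jitter_sd, mz.size)
    precursor = Descriptors.ExactMolWt(molecule) + PROTON_MASS
    if spec.decoy_peaks > 0:
        lo = 50.0
        decoys = rng.uniform(lo, max(precursor, lo + 1), spec.decoy_peaks)
        mz = np.concatenate([mz, decoys])
    intensity = np.full(mz.size, 100.0)
    return Spectrum(
        identifier=identifier,
        precursor_mz=precursor,
        charge=1,
        mz=mz,
        intensity=intensity,
    )


def spec_to_dict(spec: FixtureSpec) -> dict:
    return dataclasses.asdict(spec)
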