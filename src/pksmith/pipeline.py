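"""End-to-end orchestration: BGC -> candidate structures -> spectral matches.

Stages: substrate-specificity prediction for every AT domain, inactive-domain
flagging, assembly-order ranking from docking-domain compatibility, core
assembly and release, combinatorial tailoring, and (optionally) spectral
search with target-decoy FDR.  Every stage is a pure function of its inputs,
the configuration, and the seed.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from . import at_specificity as atspec
from . import assembly_order as aorder
from . import spectral_search as search
from . import structure_gen as sgen
from .bgc_model import BGC, Module
from .substrate_rules import MonomerLibrary, detect_inactive_domains, module_substrate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    head_len: int = aorder.DEFAULT_HEAD_LEN
    tail_len: int = aorder.DEFAULT_TAIL_LEN
    w_forward: float = 1.0
    w_backward: float = 1.0
    top_orders: int = 1
    order_cap: int = 100
    candidate_cap: int = sgen.DEFAULT_CANDIDATE_CAP
    frag_tol: float = search.DEFAULT_FRAG_TOL
    prec_tol: float = search.DEFAULT_PREC_TOL
    max_shift: float = search.DEFAULT_MAX_SHIFT
    decoy_steps: int = search.DEFAULT_DECOY_STEPS
    min_rel_intensity: float = search.DEFAULT_MIN_REL_INTENSITY

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Training-table I/O
# ---------------------------------------------------------------------------

def read_at_training_tsv(path: str | Path) -> list[tuple[atspec.SignatureProfile, str]]:
    """Columns: id, sequence_or_signature, label.  A 24-character field is
    taken as a ready signature; anything longer is aligned and extracted."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            seq = row["sequence_or_signature"].strip()
            if len(seq) == atspec.SIGNATURE_LENGTH:
                sig = atspec.SignatureProfile(seq, source_id=row["id"])
            else:
                sig = atspec.extract_signature(seq, source_id=row["id"])
            out.append((sig, row["label"].strip()))
    return out


def read_docking_tsv(path: str | Path) -> list[aorder.DockingPair]:
    """Columns: id_tail, id_head, tail_seq, head_seq, label (0/1)."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                aorder.DockingPair(
                    tail_seq=row["tail_seq"].strip(),
                    head_seq=row["head_seq"].strip(),
                    label=bool(int(row["label"])),
                    id=f"{row['id_tail']}~{row['id_head']}",
                )
            )
    return out


def train_specificity_from_signatures(
    labeled: list[tuple[atspec.SignatureProfile, str]], seed: int = 0
) -> atspec.SpecificityModel:
    encoded = [(atspec.encode_signature(sig), label) for sig, label in labeled]
    return atspec.train_specificity_model(encoded, seed=seed)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@dataclass
class ModulePrediction:
    gene_id: str
    module_index: int
    label: str | None
    probabilities: dict[str, float] = field(default_factory=dict)
    oxidation_state: str | None = None


def predict_module_labels(
    bgc: BGC, model: atspec.SpecificityModel
) -> list[ModulePrediction]:
    """AT substrate label per extension module, genomic order."""
    preds = []
    for gene in bgc.genes:
        for module in gene.modules:
            at = module.get("AT")
            if at is None:
                preds.append(ModulePrediction(gene.id, module.index, None))
                continue
            sig = atspec.extract_signature(at.sequence, source_id=gene.id)
            label, pmap = atspec.predict_specificity(
                model, atspec.encode_signature(sig)
            )
            preds.append(
                ModulePrediction(gene.id, module.index, label, pmap)
            )
    return preds


def flag_inactive(bgc: BGC) -> BGC:
    """Apply the catalytic-motif inactive-domain heuristic to every module."""
    genes = []
    for gene in bgc.genes:
        modules = [detect_inactive_domains(m) for m in gene.modules]
        genes.append(dataclasses.replace(gene, modules=modules))
    return BGC(genes=genes, tailoring_enzymes=bgc.tailoring_enzymes,
               source=bgc.source)


@dataclass
class StructureResult:
    orders: list[aorder.PathwayOrder]
    n_candidate_orders: int
    predictions: list[ModulePrediction]
    cores: list[sgen.CoreStructure]
    candidates: list[sgen.CandidateCompound]
    report: sgen.EnumerationReport | None
    starter_unknown: bool = False


def build_cores_for_order(
    bgc: BGC,
    order: list[str],
    predictions: dict[tuple[str, int], str],
    library: MonomerLibrary,
    te_present: bool,
    pathway_rank: int = 0,
) -> tuple[list[sgen.CoreStructure], bool]:
    """Assemble and release core structures for one gene order."""
    modules: list[tuple[str, Module]] = []
    for gid in order:
        for m in bgc.gene(gid).modules:
            modules.append((gid, m))
    starter_unknown = bool(modules) and modules[0][1].get("AT") is None
    substrates = []
    for gid, m in modules:
        if m.get("AT") is None:
            continue  # non-extension module: unknown starter or loading gap
        label = predictions[(gid, m.index)]
        substrates.append(module_substrate(m, label, library))
    chain = sgen.assemble_core(substrates, starter_unknown=starter_unknown)
    cores = sgen.release_products(chain, te_present, pathway_rank=pathway_rank)
    return cores, starter_unknown


def predict_structures(
    bgc: BGC,
    specificity_model: atspec.SpecificityModel,
    interaction_model: aorder.InteractionModel | None = None,
    rule_db: sgen.RuleDatabase | None = None,
    config: RunConfig | None = None,
    library: MonomerLibrary | None = None,
) -> StructureResult:
    """Genomics-only half of the pipeline: BGC to candidate mature compounds."""
    config = config or RunConfig()
    library = library or MonomerLibrary.load()
    rule_db = rule_db if rule_db is not None else sgen.load_modification_db()
    bgc = flag_inactive(bgc)
    predictions = predict_module_labels(bgc, specificity_model)
    pred_map = {
        (p.gene_id, p.module_index): p.label
        for p in predictions
        if p.label is not None
    }
    params = aorder.PathwayScoreParams(config.w_forward, config.w_backward)
    if len(bgc.genes) > 1:
        if interaction_model is None:
            raise aorder.AssemblyError(
                "multi-gene BGC requires a docking interaction model"
            )
        ranking = aorder.rank_pathways(
            bgc,
            model=interaction_model,
            params=params,
            cap=config.order_cap,
        )
    else:
        ranking = aorder.rank_pathways(bgc, pair_score={}, params=params, cap=1)
    te_present = any(
        m.get("TE") is not None for g in bgc.genes for m in g.modules
    )
    cores: list[sgen.CoreStructure] = []
    starter_unknown = False
    for order_obj in ranking.orders[: config.top_orders]:
        oc, su = build_cores_for_order(
            bgc, order_obj.permutation, pred_map, library, te_present,
            pathway_rank=order_obj.rank,
        )
        cores.extend(oc)
        starter_unknown = starter_unknown or su
    tags = [t.kind for t in bgc.tailoring_enzymes]
    stream, report = sgen.enumerate_candidates(
        cores, tags, rule_db, cap=config.candidate_cap
    )
    candidates = list(stream)
    return StructureResult(
        orders=ranking.orders,
        n_candidate_orders=ranking.n_candidates,
        predictions=predictions,
        cores=cores,
        candidates=candidates,
        report=report,
        starter_unknown=starter_unknown,
    )


def search_spectra(
    candidates: list[sgen.CandidateCompound],
    spectra: list[search.Spectrum],
    config: RunConfig | None = None,
    mode: str = "exact",
) -> list[search.CompoundSpectrumMatch]:
    """Score every candidate against every spectrum; best matches first."""
    config = config or RunConfig()
    if mode not in ("exact", "variable"):
        raise ValueError(f"unknown search mode {mode!r}")
    matches = []
    frag_cache: dict[str, search.FragmentSet] = {}
    for ci, cand in enumerate(candidates):
        cid = cand.smiles
        if cid not in frag_cache:
            frag_cache[cid] = search.fragment(cand.mol, depth=2)
        frags = frag_cache[cid]
        for spec in spectra:
            if mode == "exact":
                m = search.score_exact(
                    cand.mol, spec,
                    frag_tol=config.frag_tol, prec_tol=config.prec_tol,
                    compound_id=f"cand{ci}",
                    min_rel_intensity=config.min_rel_intensity,
                    fragments=frags,
                )
            else:
                m = search.score_variable(
                    cand.mol, spec,
                    frag_tol=config.frag_tol, max_shift=config.max_shift,
                    prec_tol=config.prec_tol, compound_id=f"cand{ci}",
                    min_rel_intensity=config.min_rel_intensity,
                    fragments=frags,
                )
            if m is not None:
                matches.append(m)
    matches.sort(key=lambda m: (-m.score, m.compound_id, m.spectrum_id))
    return matches


def run_fdr(
    candidates: list[sgen.CandidateCompound],
    spectra: list[search.Spectrum],
    threshold: float,
    config: RunConfig | None = None,
    mode: str = "exact",
    seed: int = 0,
) -> search.FdrResult:
    """Decoy the candidate set, search both, and estimate FDR at a threshold."""
    config = config or RunConfig()
    target_keys = {Chem.MolToInchiKey(c.mol) for c in candidates}
    decoys = []
    for i, cand in enumerate(candidates):
        decoy = search.generate_decoy(
            cand.mol, steps=config.decoy_steps, seed=seed * 100_003 + i,
            targets=target_keys,
        )
        decoys.append(
            sgen.CandidateCompound(
                mol=decoy,
                smiles=Chem.MolToSmiles(decoy),
                applied=cand.applied,
                monoisotopic_mass=cand.monoisotopic_mass,
                core=cand.core,
            )
        )
    target_matches = search_spectra(candidates, spectra, config, mode)
    decoy_matches = search_spectra(decoys, spectra, config, mode)
    return search.estimate_fdr(target_matches, decoy_matches, threshold)
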