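"""AT-domain substrate-specificity prediction.

The substrate an acyltransferase (AT) domain selects (malonyl-CoA, ``mal``;
methylmalonyl-CoA, ``mmal``; rarer extenders) is largely determined by a small
set of active-site residues.  This module extracts a 24-residue active-site
signature by pairwise alignment to a packaged reference profile, one-hot
encodes it (24 positions x 20 amino acids = 480 bits), and trains an
extremely-randomized-trees classifier (150 trees, max depth 10) on labelled
signatures.  Evaluation helpers bin test points by their minimum Hamming
distance to the training set (bin Bk+ = points at distance >= k from every
training point) and run shuffled five-fold cross-validation.

The packaged reference profile is a synthetic stand-in (see
``data/at_reference_synthetic.fasta``): a deterministic sequence with 24
marked columns, sufficient for signature extraction mechanics and for the
fixture-driven tests; real analyses should supply a structurally derived
reference via ``load_reference``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import joblib
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from sklearn.ensemble import ExtraTreesClassifier

SIGNATURE_LENGTH = 24
N_AMINO = 20
ENCODED_LENGTH = SIGNATURE_LENGTH * N_AMINO  # 480
GAP = "-"
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}

MODEL_FORMAT_VERSION = 1


class SpecificityError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureProfile:
    """A length-24 active-site signature ('-' marks unaligned positions)."""

    residues: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) != SIGNATURE_LENGTH:
            raise SpecificityError(
                f"signature must have length {SIGNATURE_LENGTH}, "
                f"got {len(self.residues)}"
            )


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference sequence plus the 24 marked active-site column indices."""

    sequence: str
    columns: tuple[int, ...]
    id: str = "reference"

    def __post_init__(self) -> None:
        if len(self.columns) != SIGNATURE_LENGTH:
            raise SpecificityError(
                f"reference must mark exactly {SIGNATURE_LENGTH} columns"
            )
        if max(self.columns) >= len(self.sequence):
            raise SpecificityError("marked column beyond reference length")

    @property
    def signature(self) -> SignatureProfile:
        return SignatureProfile(
            "".join(self.sequence[c] for c in self.columns), self.id
        )


def load_reference(
    fasta: str | Path | None = None, columns_json: str | Path | None = None
) -> ReferenceProfile:
    """Load a reference profile; defaults to the packaged synthetic one."""
    if fasta is None:
        data = resources.files("pksmith") / "data"
        fasta = str(data / "at_reference_synthetic.fasta")
        columns_json = str(data / "at_reference_columns.json")
    rec = next(SeqIO.parse(str(fasta), "fasta"))
    with open(columns_json) as fh:
        meta = json.load(fh)
    return ReferenceProfile(
        sequence=str(rec.seq), columns=tuple(meta["columns"]), id=rec.id
    )


# ---------------------------------------------------------------------------
# Signature extraction
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    # free end gaps: the AT domain may be embedded in a longer protein
    try:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def extract_signature(
    at_sequence: str,
    reference: ReferenceProfile | None = None,
    min_score: float = 0.0,
    source_id: str = "",
) -> SignatureProfile:
    """Residues of ``at_sequence`` aligned to the 24 marked reference columns.

    Pairwise global alignment (BLOSUM62, affine gaps open 10 / extend 1, free
    end gaps) against the reference; reference columns with no aligned query
    residue yield the gap character.  An alignment score below ``min_score``
    raises ("not an AT domain").
    """
    if reference is None:
        reference = load_reference()
    seq = at_sequence.upper().replace("*", "")
    if len(seq) < 50:
        raise SpecificityError("AT sequence too short (< 50 residues)")
    aligner = _make_aligner()
    aln = aligner.align(reference.sequence, seq)
    best = aln[0]
    if best.score < min_score:
        raise SpecificityError(
            f"alignment score {best.score:.1f} below floor {min_score}: "
            "not an AT domain"
        )
    # map reference column -> query index from the aligned blocks
    col_to_query: dict[int, int] = {}
    t_blocks, q_blocks = best.aligned
    for (ts, te), (qs, _qe) in zip(t_blocks, q_blocks):
        for off in range(te - ts):
            col_to_query[ts + off] = qs + off
    residues = "".join(
        seq[col_to_query[c]] if c in col_to_query else GAP for c in reference.columns
    )
    return SignatureProfile(residues, source_id=source_id)


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def encode_signature(sig: SignatureProfile) -> np.ndarray:
    """One-hot encode: per position a 20-bit block with a single set bit.

    Gap positions give an all-zero block; the ambiguous residue X likewise
    (with a warning), preserving the fixed 480-bit length.
    """
    bits = np.zeros(ENCODED_LENGTH, dtype=np.uint8)
    for i, aa in enumerate(sig.residues):
        if aa == GAP:
            continue
        if aa not in _AA_INDEX:
            warnings.warn(f"non-standard residue {aa!r} at position {i}: zero block")
            continue
        bits[i * N_AMINO + _AA_INDEX[aa]] = 1
    return bits


def decode_signature(bits: np.ndarray, source_id: str = "") -> SignatureProfile:
    """Inverse of :func:`encode_signature` (all-zero blocks decode to '-')."""
    if bits.shape != (ENCODED_LENGTH,):
        raise SpecificityError(f"encoded signature must have length {ENCODED_LENGTH}")
    chars = []
    for i in range(SIGNATURE_LENGTH):
        block = bits[i * N_AMINO : (i + 1) * N_AMINO]
        hot = np.flatnonzero(block)
        if hot.size == 0:
            chars.append(GAP)
        elif hot.size == 1:
            chars.append(_AA_ORDER[hot[0]])
        else:
            raise SpecificityError(f"position {i}: multiple set bits")
    return SignatureProfile("".join(chars), source_id)


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class SpecificityModel:
    estimator: ExtraTreesClassifier
    label_vocabulary: list[str]
    hyperparameters: dict = field(default_factory=dict)
    training_fingerprint: str = ""

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "estimator": self.estimator,
                "label_vocabulary": self.label_vocabulary,
                "hyperparameters": self.hyperparameters,
                "training_fingerprint": self.training_fingerprint,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SpecificityModel":
        obj = joblib.load(path)
        if obj.get("format_version") != MODEL_FORMAT_VERSION:
            raise SpecificityError(
                f"unsupported model format {obj.get('format_version')}"
            )
        return cls(
            estimator=obj["estimator"],
            label_vocabulary=obj["label_vocabulary"],
            hyperparameters=obj["hyperparameters"],
            training_fingerprint=obj["training_fingerprint"],
        )


def _fingerprint(X: np.ndarray, y: list[str]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update("\x00".join(y).encode())
    return h.hexdigest()[:16]


def train_specificity_model(
    labeled: list[tuple[np.ndarray, str]],
    n_trees: int = 150,
    max_depth: int = 10,
    seed: int = 0,
) -> SpecificityModel:
    """Fit the extremely-randomized-trees specificity classifier.

    Defaults (150 trees, max depth 10) are the operating point used for AT
    substrate classification; predictions are deterministic given ``seed``.
    """
    if not labeled:
        raise SpecificityError("empty training set")
    X = np.vstack([bits for bits, _ in labeled]).astype(np.uint8)
    y = [label for _, label in labeled]
    vocab = sorted(set(y))
    if len(vocab) < 2:
        warnings.warn(
            f"single-label training set ({vocab[0]!r}): degenerate model "
            "that always predicts that label"
        )
    est = ExtraTreesClassifier(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed
    )
    est.fit(X, y)
    return SpecificityModel(
        estimator=est,
        label_vocabulary=list(est.classes_),
        hyperparameters={"n_trees": n_trees, "max_depth": max_depth, "seed": seed},
        training_fingerprint=_fingerprint(X, y),
    )


def predict_specificity(
    model: SpecificityModel, bits: np.ndarray
) -> tuple[str, dict[str, float]]:
    """Predicted label (ties broken lexicographically) and probability map."""
    if bits.shape != (ENCODED_LENGTH,):
        raise SpecificityError(f"encoded signature must have length {ENCODED_LENGTH}")
    probs = model.estimator.predict_proba(bits.reshape(1, -1))[0]
    pmap = dict(zip(model.label_vocabulary, (float(p) for p in probs)))
    best_p = max(pmap.values())
    label = min(l for l, p in pmap.items() if p == best_p)
    return label, pmap


# ---------------------------------------------------------------------------
# Hamming-distance evaluation bins
# ---------------------------------------------------------------------------

@dataclass
class BinReport:
    """Per-k membership (indices into the test set) and accuracy."""

    membership: dict[int, list[int]]
    counts: dict[int, int]
    accuracy: dict[int, float | None]


def _sig_matrix(sigs: list[SignatureProfile]) -> np.ndarray:
    return np.array([[ord(c) for c in s.residues] for s in sigs], dtype=np.int16)


def min_hamming_distances(
    train_sigs: list[SignatureProfile], test_sigs: list[SignatureProfile]
) -> np.ndarray:
    """Per test signature, the minimum Hamming distance to any training one."""
    if not train_sigs:
        raise SpecificityError("empty training set")
    T = _sig_matrix(train_sigs)
    Q = _sig_matrix(test_sigs)
    # (n_test, n_train) pairwise distances over 24 positions
    d = (Q[:, None, :] != T[None, :, :]).sum(axis=2)
    return d.min(axis=1)


def hamming_bins(
    train_sigs: list[SignatureProfile],
    test_sigs: list[SignatureProfile],
    ks: list[int],
    test_labels: list[str] | None = None,
    predictions: list[str] | None = None,
) -> BinReport:
    """Bin Bk+ = test points at Hamming distance >= k from all training points."""
    dmin = min_hamming_distances(train_sigs, test_sigs)
    membership: dict[int, list[int]] = {}
    counts: dict[int, int] = {}
    accuracy: dict[int, float | None] = {}
    for k in ks:
        idx = [int(i) for i in np.flatnonzero(dmin >= k)]
        membership[k] = idx
        counts[k] = len(idx)
        if test_labels is not None and predictions is not None and idx:
            hits = sum(1 for i in idx if test_labels[i] == predictions[i])
            accuracy[k] = hits / len(idx)
        else:
            accuracy[k] = None
    return BinReport(membership=membership, counts=counts, accuracy=accuracy)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def crossvalidate(
    dataset: list[tuple[np.ndarray, str]],
    folds: int = 5,
    shuffles: int = 5,
    seed: int = 0,
    n_trees: int = 150,
    max_depth: int = 10,
) -> dict:
    """Shuffled k-fold cross-validation of the specificity classifier.

    Each shuffle partitions the data into ``folds`` near-equal disjoint test
    folds; accuracy is the mean over shuffles x folds.  The confusion matrix
    is averaged across shuffles and rounded to the nearest integer for
    display.  Deterministic given ``seed``.
    """
    n = len(dataset)
    if folds > n:
        raise SpecificityError(f"folds={folds} exceeds dataset size {n}")
    X = np.vstack([bits for bits, _ in dataset]).astype(np.uint8)
    y = np.array([label for _, label in dataset])
    labels = sorted(set(y))
    lab_idx = {l: i for i, l in enumerate(labels)}
    rng = np.random.default_rng(seed)
    fold_accs: list[float] = []
    confusion_sum = np.zeros((len(labels), len(labels)), dtype=float)
    for s in range(shuffles):
        perm = rng.permutation(n)
        fold_sizes = np.full(folds, n // folds)
        fold_sizes[: n % folds] += 1
        start = 0
        for fs in fold_sizes:
            test_idx = perm[start : start + fs]
            start += fs
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            est = ExtraTreesClassifier(
                n_estimators=n_trees,
                max_depth=max_depth,
                random_state=seed * 1000 + s,
            )
            est.fit(X[train_mask], y[train_mask])
            pred = est.predict(X[test_idx])
            fold_accs.append(float(np.mean(pred == y[test_idx])))
            for t, p in zip(y[test_idx], pred):
                confusion_sum[lab_idx[t], lab_idx[p]] += 1
    confusion = np.rint(confusion_sum / shuffles).astype(int)
    return {
        "accuracy": float(np.mean(fold_accs)),
        "fold_accuracies": fold_accs,
        "labels": labels,
        "confusion": confusion,
    }
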