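"""Pocket CTD descriptors (147) and ligand physicochemical descriptors (196).

The pocket is summarized by Composition/Transition/Distribution (CTD)
statistics of its amino-acid sequence: each of seven physicochemical
properties partitions the 20 amino acids into three classes, and per
property the descriptor records class percentages (C, 3 values), the
frequency of adjacent class transitions (T, 3 values), and the sequence
positions at which each class reaches its first / 25% / 50% / 75% / 100%
occurrence (D, 15 values) — 21 per property, 147 in total.

Ligands are summarized by a frozen 196-name registry of 2D descriptors
evaluated with RDKit (see :mod:`deeplip._registry`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from ._registry import LIGAND_DESCRIPTOR_NAMES, LIGAND_REGISTRY_VERSION
from .errors import AlphabetError, EmptyMoleculeError, SequenceLengthError
from .structure_io import Ligand, ligand_to_rdkit

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

POCKET_REGISTRY_VERSION = "ctd147-v1"


@dataclass(frozen=True)
class PropertyGrouping:
    """A partition of the 20 standard amino acids into 3 classes."""
    name: str
    groups: Tuple[str, str, str]  # residue letters of class 1, 2, 3

    def __post_init__(self):
        joined = "".join(self.groups)
        if sorted(joined) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"grouping {self.name!r} is not a partition of the "
                "20-letter alphabet")

    def class_of(self, letter: str) -> int:
        for k, g in enumerate(self.groups):
            if letter in g:
                return k
        raise AlphabetError(f"letter {letter!r} outside the amino-acid "
                            "alphabet")


#: The canonical three-class partitions used by standard CTD toolkits.
CTD_GROUPINGS: Tuple[PropertyGrouping, ...] = (
    PropertyGrouping("hydrophobicity", ("RKEDQN", "GASTPHY", "CLVIMFW")),
    PropertyGrouping("normalized_vdw_volume", ("GASTPDC", "NVEQIL", "MHKFRYW")),
    PropertyGrouping("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    PropertyGrouping("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    PropertyGrouping("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    PropertyGrouping("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    PropertyGrouping("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MSPTHY")),
)


@dataclass
class DescriptorVector:
    """Fixed-length named numeric feature vector."""
    names: List[str]
    values: np.ndarray
    registry_version: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names/values length mismatch")

    def __len__(self):
        return len(self.names)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _classes(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    try:
        return np.array([grouping.class_of(c) for c in sequence], dtype=int)
    except AlphabetError:
        bad = sorted({c for c in sequence if c not in AMINO_ACIDS})
        raise AlphabetError(f"sequence contains non-amino-acid letters {bad}")


def ctd_composition(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Percent of residues in each of the 3 classes: C_g = 100 * n_g / N."""
    if len(sequence) < 1:
        raise SequenceLengthError("composition needs a nonempty sequence")
    cls = _classes(sequence, grouping)
    counts = np.bincount(cls, minlength=3).astype(float)
    return 100.0 * counts / len(sequence)


def ctd_transition(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Percent of adjacent pairs crossing classes, ordered (T12, T13, T23):
    T_gh = 100 * (n_gh + n_hg) / (N - 1)."""
    if len(sequence) < 2:
        raise SequenceLengthError("transition needs a sequence of length >= 2")
    cls = _classes(sequence, grouping)
    pairs = np.stack([cls[:-1], cls[1:]])
    lo, hi = pairs.min(axis=0), pairs.max(axis=0)
    out = np.zeros(3)
    for k, (g, h) in enumerate(((0, 1), (0, 2), (1, 2))):
        out[k] = np.sum((lo == g) & (hi == h))
    return 100.0 * out / (len(sequence) - 1)


def ctd_distribution(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Per class, the sequence positions (as 100*pos/N, 1-based) of the
    first, 25%, 50%, 75% and 100% occurrence; absent classes yield zeros.

    The k-th quartile position is the ceil(k * n_g / 4)-th occurrence.
    """
    if len(sequence) < 1:
        raise SequenceLengthError("distribution needs a nonempty sequence")
    cls = _classes(sequence, grouping)
    n = len(sequence)
    out = np.zeros(15)
    for g in range(3):
        positions = np.nonzero(cls == g)[0] + 1  # 1-based
        ng = positions.size
        if ng == 0:
            continue
        idx = [1] + [max(1, math.ceil(k * ng / 4.0)) for k in (1, 2, 3, 4)]
        out[5 * g:5 * g + 5] = 100.0 * positions[np.array(idx) - 1] / n
    return out


_D_LABELS = ("first", "p25", "p50", "p75", "p100")


def pocket_ctd(sequence: str) -> DescriptorVector:
    """The full 147-dimensional CTD vector: 7 properties x (3C + 3T + 15D),
    property-major, C/T/D blocks within each property."""
    names: List[str] = []
    values: List[float] = []
    for grouping in CTD_GROUPINGS:
        p = grouping.name
        values.extend(ctd_composition(sequence, grouping))
        names.extend(f"{p}.C{g + 1}" for g in range(3))
        values.extend(ctd_transition(sequence, grouping))
        names.extend(f"{p}.T{a}{b}" for a, b in ("12", "13", "23"))
        values.extend(ctd_distribution(sequence, grouping))
        names.extend(f"{p}.D{g + 1}.{lab}" for g in range(3)
                     for lab in _D_LABELS)
    vec = DescriptorVector(names, np.array(values), POCKET_REGISTRY_VERSION)
    assert len(vec) == 147
    return vec


# ---------------------------------------------------------------------------
# Ligand descriptors
# ---------------------------------------------------------------------------

_warned_names: set = set()


def descriptor_registry() -> Tuple[Tuple[str, ...], str]:
    """The frozen ordered list of 196 ligand descriptor names + version."""
    return LIGAND_DESCRIPTOR_NAMES, LIGAND_REGISTRY_VERSION


def ligand_descriptors(ligand: Ligand) -> DescriptorVector:
    """Evaluate the frozen 196-descriptor registry on a ligand.

    Descriptors that fail to evaluate or return non-finite values are
    imputed to 0 (warned once per descriptor name per process).
    """
    from rdkit.Chem import Descriptors as RDDescriptors

    if not ligand.atoms:
        raise EmptyMoleculeError("ligand has no atoms")
    mol = ligand_to_rdkit(ligand, sanitize=True)
    fn_map = dict(RDDescriptors._descList)
    values = np.zeros(len(LIGAND_DESCRIPTOR_NAMES))
    for k, name in enumerate(LIGAND_DESCRIPTOR_NAMES):
        try:
            v = float(fn_map[name](mol))
        except Exception:
            v = float("nan")
        if not np.isfinite(v):
            if name not in _warned_names:
                _warned_names.add(name)
                logger.warning("descriptor %s non-finite for ligand %s; "
                               "imputed 0", name, ligand.name)
            v = 0.0
        values[k] = v
    return DescriptorVector(list(LIGAND_DESCRIPTOR_NAMES), values,
                            LIGAND_REGISTRY_VERSION)


def descriptors_to_csv(vectors: Dict[str, DescriptorVector], path) -> None:
    """Write descriptor vectors as CSV: header = id + descriptor names."""
    import csv

    vectors = dict(vectors)
    first = next(iter(vectors.values()))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id"] + list(first.names))
        for sid, vec in vectors.items():
            writer.writerow([sid] + [repr(v) for v in vec.values.tolist()])
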