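"""Descriptor computation and the Z/N descriptor filters.

Descriptors are produced by a pluggable backend so the protocol itself stays
descriptor-agnostic.  Two backends ship with the package: ``rdkit2d`` (the
full RDKit 2D descriptor set, ~210 descriptors, no geometry optimisation)
and ``toy-counts`` (heavy-atom and ring counts, used in tests and examples).
A precomputed descriptor CSV can bypass the backend entirely.

Two filters shape the matrix the matching modules see:

* **Z filter** — drop every descriptor whose percentage of exactly-zero
  values (among observed entries) exceeds Z.  Near-constant-zero descriptors
  carry no contrast for +/-5% tolerance matching.
* **top-N selection** — per cell line, keep the N descriptors whose
  within-template relative dispersion (mean over non-empty templates of
  sigma / (|mu| + eps)) is smallest: tight descriptors make the mu +/- sigma
  profile match discriminative.
"""

from __future__ import annotations

import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .datamodel import AapError, DescriptorMatrix, StructureRecord

if TYPE_CHECKING:  # pragma: no cover
    from .templates import Template

logger = logging.getLogger("aap")

#: Epsilon guarding the relative-dispersion ranking against mu == 0.
RANK_EPS = 1e-9

#: Gaussian smoothing modes accepted by the template-matching score.
G_MODES = ("a", "b", "c")


@dataclass(frozen=True)
class CLParams:
    """Tunable parameters of the template (CL) module.

    N
        Number of dynamically selected descriptors retained per cell line
        (clamped to the number available).
    Z
        Maximum percentage of zero values per descriptor, in [0, 100];
        columns above the threshold are dropped before matching.
    G
        Smoothing mode for the template score: ``"a"`` is the hard
        mu +/- sigma indicator, ``"b"`` and ``"c"`` are progressively wider
        Gaussian kernels.
    """

    N: int
    Z: float = 50.0
    G: str = "a"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise AapError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.Z <= 100.0:
            raise AapError(f"Z must be in [0, 100], got {self.Z}")
        if self.G not in G_MODES:
            raise AapError(f"G must be one of {G_MODES}, got {self.G!r}")


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------


class DescriptorBackend(ABC):
    """Maps one structure record to one real descriptor vector.

    Implementations must be deterministic: the same structure payload always
    yields the same vector.  Individual descriptor failures are reported as
    NaN, never as exceptions.
    """

    backend_id: str
    descriptor_names: list[str]

    @abstractmethod
    def compute(self, record: StructureRecord) -> np.ndarray:
        """Return one float vector of length ``len(descriptor_names)``."""


def _mol_from_record(record: StructureRecord):
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    if record.fmt == "sdf":
        return Chem.MolFromMolBlock(record.structure, sanitize=True)
    return Chem.MolFromSmiles(record.structure)


class RDKit2DBackend(DescriptorBackend):
    """All RDKit 2D descriptors (Descriptors._descList), computed per molecule."""

    backend_id = "rdkit2d"

    def __init__(self) -> None:
        from rdkit.Chem import Descriptors

        self._desc_list = list(Descriptors._descList)
        self.descriptor_names = [name for name, _ in self._desc_list]

    def compute(self, record: StructureRecord) -> np.ndarray:
        mol = _mol_from_record(record)
        out = np.full(len(self._desc_list), np.nan)
        if mol is None:
            return out
        for k, (_, fn) in enumerate(self._desc_list):
            try:
                v = float(fn(mol))
            except Exception:
                continue
            if np.isfinite(v):
                out[k] = v
        return out


class ToyCountBackend(DescriptorBackend):
    """Minimal counting backend (heavy atoms, rings) for tests and demos."""

    backend_id = "toy-counts"
    descriptor_names = ["atom_count", "ring_count"]

    def compute(self, record: StructureRecord) -> np.ndarray:
        mol = _mol_from_record(record)
        if mol is None:
            return np.array([np.nan, np.nan])
        from rdkit.Chem import rdMolDescriptors

        return np.array(
            [float(mol.GetNumAtoms()), float(rdMolDescriptors.CalcNumRings(mol))]
        )


_BACKENDS: dict[str, type[DescriptorBackend]] = {
    RDKit2DBackend.backend_id: RDKit2DBackend,
    ToyCountBackend.backend_id: ToyCountBackend,
}


def register_backend(cls: type[DescriptorBackend]) -> type[DescriptorBackend]:
    """Register a backend class under its ``backend_id`` (usable as decorator)."""
    _BACKENDS[cls.backend_id] = cls
    return cls


def get_backend(backend_id: str) -> DescriptorBackend:
    if backend_id not in _BACKENDS:
        raise AapError(
            f"unknown descriptor backend {backend_id!r}; "
            f"available: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[backend_id]()


# cache keyed by (backend_id, structure payload): resubmitting a structure
# is a dictionary lookup, mirroring a descriptor server's caching layer
_DESCRIPTOR_CACHE: dict[tuple[str, str], np.ndarray] = {}


def clear_descriptor_cache() -> None:
    _DESCRIPTOR_CACHE.clear()


def compute_descriptors(
    structures: Sequence[StructureRecord], backend: DescriptorBackend
) -> DescriptorMatrix:
    """Compute the descriptor matrix for a batch of structures.

    One row per structure, one column per backend descriptor.  A failure for
    a single (structure, descriptor) pair yields NaN; a structure the backend
    cannot parse at all yields an all-NaN row plus a logged warning — the
    batch never aborts.
    """
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise AapError("duplicate compound ids in structure batch")
    rows = []
    for rec in structures:
        key = (backend.backend_id, rec.structure)
        if key in _DESCRIPTOR_CACHE:
            vec = _DESCRIPTOR_CACHE[key]
        else:
            vec = np.asarray(backend.compute(rec), dtype=float)
            if vec.shape != (len(backend.descriptor_names),):
                raise AapError(
                    f"backend {backend.backend_id!r} returned a vector of length "
                    f"{vec.shape} for {rec.id!r}"
                )
            _DESCRIPTOR_CACHE[key] = vec
        if np.all(np.isnan(vec)):
            logger.warning(
                "structure %r could not be processed by backend %r; "
                "row is all-missing", rec.id, backend.backend_id,
            )
        rows.append(vec)
    return DescriptorMatrix.from_arrays(ids, backend.descriptor_names, np.vstack(rows))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def zero_filter(matrix: DescriptorMatrix, Z: float) -> DescriptorMatrix:
    """Drop descriptors whose zero percentage (among observed values) exceeds Z.

    The comparison is strict: a column with exactly Z% zeros is kept.
    Columns with no observed values count as 0% zeros.  Survivor order is
    preserved; dropping every column raises an error advising a larger Z.
    """
    if not 0.0 <= Z <= 100.0:
        raise AapError(f"Z must be in [0, 100], got {Z}")
    vals = matrix.values.to_numpy()
    observed = ~np.isnan(vals)
    n_obs = observed.sum(axis=0)
    n_zero = ((vals == 0.0) & observed).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_obs > 0, n_zero / np.maximum(n_obs, 1), 0.0)
    keep = frac * 100.0 <= Z
    if not keep.any():
        raise AapError(
            f"zero filter at Z={Z} removed every descriptor; increase Z"
        )
    return DescriptorMatrix(matrix.values.loc[:, keep])


def rank_descriptors(
    templates: Iterable["Template"], descriptor_list: Sequence[str]
) -> list[str]:
    """Rank descriptors by mean within-template relative dispersion, ascending.

    For each descriptor the score is the mean, over non-empty templates where
    the descriptor is defined, of sigma / (|mu| + eps).  Descriptors defined
    in no template sort last; ties break lexicographically by name.
    """
    d = len(descriptor_list)
    total = np.zeros(d)
    count = np.zeros(d, dtype=int)
    for t in templates:
        if t.member_count == 0:
            continue
        defined = ~np.isnan(t.mu)
        disp = np.where(defined, t.sigma / (np.abs(t.mu) + RANK_EPS), 0.0)
        total += np.where(defined, disp, 0.0)
        count += defined
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(count > 0, total / np.maximum(count, 1), np.inf)
    order = sorted(range(d), key=lambda k: (score[k], descriptor_list[k]))
    return [descriptor_list[k] for k in order]


def select_top_descriptors(
    matrix: DescriptorMatrix,
    templates: Iterable["Template"],
    N: int,
) -> list[str]:
    """Select the N most informative descriptors for one cell line.

    ``templates`` are that cell line's activity-bin templates built on
    ``matrix``'s columns.  Returns min(N, available) names; deterministic and
    invariant under row permutation of the training matrix.
    """
    if N < 1:
        raise AapError(f"N must be >= 1, got {N}")
    ranked = rank_descriptors(templates, matrix.col_ids)
    return ranked[: min(N, len(ranked))]
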