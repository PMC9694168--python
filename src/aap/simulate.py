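"""Synthetic descriptor/activity fixtures with planted template structure.

The generator emulates the statistical assumption the template module is
built on: compounds whose pGI50 falls in the same 0.1-unit activity bin
share a descriptor profile.  Each of the 42 bins gets a latent mean vector
(shared across cell lines — a compound has a single descriptor vector, so
per-cell-line-independent profiles would be mutually inconsistent); means
are drawn uniformly in a box and re-drawn until every pair is at least
``between_separation`` apart.  A compound is assigned one bin, draws its
descriptors from that bin's (mean, diagonal within_sigma^2) Gaussian, and
draws an independent within-bin activity value per cell line (uniform inside
the bin; the open-ended edge bins sample 3-4 and 8-9).

Two kinds of planted structure exercise the two prediction routes:

* **near-duplicates** — a fraction of compounds are clones of earlier ones
  with <=1% multiplicative descriptor jitter (well inside the 5% similarity
  tolerance) that inherit the parent's activity row and missingness pattern;
* **missingness** — activity entries are masked at ``missing_rate``.

Fresh query draws from the same latent templates carry their true bin label
so bin-recovery rates can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import AapError, ActivityMatrix, DescriptorMatrix
from .templates import ALL_BINS, N_BINS

#: Default mini-panel: nine cell lines across three tumour-type subpanels.
DEFAULT_CELL_LINES: tuple[tuple[str, str], ...] = (
    ("LEU-1", "leukemia"),
    ("LEU-2", "leukemia"),
    ("LEU-3", "leukemia"),
    ("MEL-1", "melanoma"),
    ("MEL-2", "melanoma"),
    ("MEL-3", "melanoma"),
    ("REN-1", "renal"),
    ("REN-2", "renal"),
    ("REN-3", "renal"),
)

# activity density outside the regular [4, 8] range
EDGE_LOW_RANGE = (3.0, 4.0)
EDGE_HIGH_RANGE = (8.0, 9.0)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but realistic desk-scale screen: 240 compounds
    by 60 descriptors over a nine-line, three-subpanel panel; descriptor
    means in [20, 40] with unit within-template spread and a minimum
    between-template separation of 15 (so same-bin compounds are similar but
    distinct under the 5% tolerance); 10% cloned near-duplicates and 10%
    unassayed activity entries, matching the sparsity of a public screen
    dump.
    """

    n_compounds: int = 240
    n_descriptors: int = 60
    cell_lines: tuple[tuple[str, str], ...] = DEFAULT_CELL_LINES
    bin_occupancy: np.ndarray | None = None   # probability per bin 0..41
    within_sigma: float = 1.0
    between_separation: float | None = None   # default: 2 * sqrt(n_descriptors)
    duplicate_fraction: float = 0.1
    missing_rate: float = 0.1
    mean_low: float = 20.0
    mean_high: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1 or self.n_descriptors < 1:
            raise AapError("n_compounds and n_descriptors must be positive")
        if self.within_sigma <= 0:
            raise AapError("within_sigma must be > 0")
        if self.between_separation is None:
            # keeps the per-descriptor mean offset between any two templates
            # near 2 * within_sigma regardless of dimensionality
            self.between_separation = 2.0 * float(np.sqrt(self.n_descriptors))
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise AapError("duplicate_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise AapError("missing_rate must be in [0, 1]")
        if self.bin_occupancy is None:
            self.bin_occupancy = np.full(N_BINS, 1.0 / N_BINS)
        self.bin_occupancy = np.asarray(self.bin_occupancy, dtype=float)
        if self.bin_occupancy.shape != (N_BINS,):
            raise AapError(f"bin_occupancy must have length {N_BINS}")
        if np.any(self.bin_occupancy < 0) or not np.isclose(
            self.bin_occupancy.sum(), 1.0
        ):
            raise AapError("bin_occupancy must be a probability distribution")


@dataclass
class GroundTruth:
    """What the generator planted: latent means and true assignments."""

    template_means: np.ndarray           # (42, n_descriptors)
    bin_of: dict[str, int]               # compound id -> bin index
    parent_of: dict[str, str] = field(default_factory=dict)  # clone id -> parent id


def _draw_template_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Latent per-bin mean vectors with guaranteed pairwise separation.

    Sequential rejection: each mean is redrawn until it clears every
    previously placed one.
    """
    means = np.empty((N_BINS, spec.n_descriptors))
    for b in range(N_BINS):
        for attempt in range(2000):
            cand = rng.uniform(spec.mean_low, spec.mean_high, spec.n_descriptors)
            if b == 0 or np.sqrt(
                ((means[:b] - cand) ** 2).sum(axis=1)
            ).min() >= spec.between_separation:
                means[b] = cand
                break
        else:
            raise AapError(
                f"could not place {N_BINS} template means at separation "
                f">= {spec.between_separation} with {spec.n_descriptors} "
                f"descriptors in [{spec.mean_low}, {spec.mean_high}]; lower "
                f"the separation or add descriptors"
            )
    return means


def _draw_activity_in_bin(
    bin_index: int, rng: np.random.Generator, size: int
) -> np.ndarray:
    if bin_index == 0:
        return rng.uniform(*EDGE_LOW_RANGE, size=size)
    if bin_index == N_BINS - 1:
        return rng.uniform(*EDGE_HIGH_RANGE, size=size)
    b = ALL_BINS[bin_index]
    return rng.uniform(b.lower, b.upper, size=size)


def generate_training(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, ActivityMatrix, GroundTruth]:
    """Generate an aligned training (descriptor, activity) pair plus truth.

    Fully reproducible from ``spec.seed``.  Clones are appended after the
    base compounds, carry <=1% multiplicative descriptor jitter, and inherit
    the parent's activity row and missingness mask (same molecule, same
    assay history).
    """
    rng = np.random.default_rng(spec.seed)
    means = _draw_template_means(spec, rng)
    n_dup = int(round(spec.duplicate_fraction * spec.n_compounds))
    n_base = spec.n_compounds - n_dup
    if n_base < 1:
        raise AapError("duplicate_fraction leaves no base compounds")
    n_lines = len(spec.cell_lines)
    width = len(str(spec.n_compounds))
    ids = [f"SYN-{i + 1:0{width}d}" for i in range(spec.n_compounds)]

    base_bins = rng.choice(N_BINS, size=n_base, p=spec.bin_occupancy)
    desc = np.empty((spec.n_compounds, spec.n_descriptors))
    act = np.empty((spec.n_compounds, n_lines))
    bin_of: dict[str, int] = {}
    for i in range(n_base):
        b = int(base_bins[i])
        desc[i] = means[b] + spec.within_sigma * rng.standard_normal(
            spec.n_descriptors
        )
        act[i] = _draw_activity_in_bin(b, rng, n_lines)
        bin_of[ids[i]] = b
    mask = rng.random((spec.n_compounds, n_lines)) < spec.missing_rate

    parent_of: dict[str, str] = {}
    parents = rng.integers(0, n_base, size=n_dup)
    for j in range(n_dup):
        i = n_base + j
        p = int(parents[j])
        jitter = rng.uniform(-0.01, 0.01, size=spec.n_descriptors)
        desc[i] = desc[p] * (1.0 + jitter)
        act[i] = act[p]
        mask[i] = mask[p]
        bin_of[ids[i]] = int(base_bins[p])
        parent_of[ids[i]] = ids[p]

    act = np.where(mask, np.nan, act)
    cl_ids = [cl for cl, _ in spec.cell_lines]
    panel_of = {cl: panel for cl, panel in spec.cell_lines}
    desc_names = [f"D{k + 1:03d}" for k in range(spec.n_descriptors)]
    return (
        DescriptorMatrix.from_arrays(ids, desc_names, desc),
        ActivityMatrix(pd.DataFrame(act, index=ids, columns=cl_ids), panel_of),
        GroundTruth(template_means=means, bin_of=bin_of, parent_of=parent_of),
    )


def activities_for_bins(
    bin_of: dict[str, int],
    cell_lines: Sequence[tuple[str, str]],
    seed: int,
) -> ActivityMatrix:
    """Draw within-bin experimental activities for labelled compounds.

    Same per-cell-line within-bin sampling as :func:`generate_training`;
    used to score predictions for fresh query draws against a ground-truth
    assay they were never part of.
    """
    rng = np.random.default_rng(seed)
    ids = list(bin_of)
    n_lines = len(cell_lines)
    act = np.vstack(
        [_draw_activity_in_bin(bin_of[i], rng, n_lines) for i in ids]
    )
    return ActivityMatrix(
        pd.DataFrame(act, index=ids, columns=[cl for cl, _ in cell_lines]),
        {cl: panel for cl, panel in cell_lines},
    )


def generate_queries(
    spec: SyntheticSpec,
    ground_truth: GroundTruth,
    k: int,
    seed: int | None = None,
    sigma_scale: float = 1.0,
) -> tuple[DescriptorMatrix, dict[str, int]]:
    """Draw k fresh query compounds from the planted templates.

    Queries are new draws (never copies of training rows) with their true
    bin labels, so bin-recovery rates can be scored.  ``sigma_scale``
    inflates the within-template spread to emulate increasingly novel
    scaffolds.  A separate ``seed`` (default: derived from ``spec.seed``)
    keeps queries independent of the training draw.
    """
    if k <= 0:
        raise AapError(f"query count must be positive, got {k}")
    rng = np.random.default_rng(spec.seed + 104729 if seed is None else seed)
    bins = rng.choice(N_BINS, size=k, p=spec.bin_occupancy)
    sigma = spec.within_sigma * sigma_scale
    width = len(str(k))
    ids = [f"QRY-{i + 1:0{width}d}" for i in range(k)]
    desc = np.empty((k, spec.n_descriptors))
    for i in range(k):
        desc[i] = ground_truth.template_means[int(bins[i])] + sigma * (
            rng.standard_normal(spec.n_descriptors)
        )
    desc_names = [f"D{j + 1:03d}" for j in range(spec.n_descriptors)]
    return (
        DescriptorMatrix.from_arrays(ids, desc_names, desc),
        {ids[i]: int(bins[i]) for i in range(k)},
    )
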