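"""Cell-lines (CL) module: binned activity templates and profile matching.

For every cell line the training compounds are partitioned into 42 activity
bins: 40 regular bins of width 0.1 pGI50 covering [4, 8] plus an underflow
bin (< 4) and an overflow bin (> 8).  Each (cell line, bin) pair becomes a
*template*: the per-descriptor mean and standard deviation of its member
compounds.  A query is scored against every template of a cell line and
inherits the representative activity of the best-matching one.

Scoring modes (the G parameter):

* ``a`` — hard indicator: a descriptor contributes 1 if its value lies in
  mu +/- sigma, else 0; the score is the mean over usable descriptors.
* ``b`` — Gaussian kernel exp(-z^2/2) with z = (v - mu)/sigma.
* ``c`` — wider Gaussian kernel exp(-z^2/8) (effective width 2 sigma).

Conventions the literature leaves open, fixed here: the boundary value 8.0
belongs to the top regular bin [7.9, 8.0], not the overflow bin; the
representative value of a regular bin is its midpoint, while the underflow
and overflow bins report the assay clamps 4.0 and 8.0; standard deviations
are population (ddof=0) with a floor of 1e-6 * max(|mu|, 1) so single-member
and constant templates remain usable in every mode.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AapError, ActivityMatrix, DescriptorMatrix
from .descriptors import CLParams, select_top_descriptors

logger = logging.getLogger("aap")

BIN_LOW = 4.0          # lower edge of the regular binning range (pGI50)
BIN_HIGH = 8.0         # upper edge of the regular binning range
BIN_WIDTH = 0.1        # width of one regular bin
N_REGULAR_BINS = 40
N_BINS = N_REGULAR_BINS + 2   # + underflow + overflow

#: Relative floor applied to template standard deviations.
SIGMA_FLOOR_REL = 1e-6

# absorbs float representation error at bin edges (values are pGI50,
# reported to at most a few decimals; 1e-7 is far below half a bin)
_EDGE_EPS = 1e-7


@dataclass(frozen=True)
class ActivityBin:
    """One pGI50 bin: half-open [lower, upper) except the closed top bin."""

    index: int
    lower: float   # -inf for the underflow bin
    upper: float   # +inf for the overflow bin
    assigned_value: float

    def contains(self, value: float) -> bool:
        return assign_bin(value) == self.index


def make_bin(index: int) -> ActivityBin:
    """Construct the bin with the given index (0 = underflow, 41 = overflow)."""
    if not 0 <= index < N_BINS:
        raise AapError(f"bin index out of range: {index}")
    if index == 0:
        return ActivityBin(0, -math.inf, BIN_LOW, BIN_LOW)
    if index == N_BINS - 1:
        return ActivityBin(N_BINS - 1, BIN_HIGH, math.inf, BIN_HIGH)
    lower = round(BIN_LOW + (index - 1) * BIN_WIDTH, 10)
    upper = round(lower + BIN_WIDTH, 10)
    return ActivityBin(index, lower, upper, round(lower + BIN_WIDTH / 2, 10))


ALL_BINS: tuple[ActivityBin, ...] = tuple(make_bin(i) for i in range(N_BINS))


def assign_bin(value: float) -> int:
    """Map a pGI50 value to its bin index (0..41).

    Values < 4 go to the underflow bin 0; values > 8 to the overflow bin 41;
    8.0 itself belongs to the top regular bin [7.9, 8.0].  Missing values are
    the caller's problem and raise.
    """
    v = float(value)
    if math.isnan(v):
        raise AapError("cannot bin a missing activity value")
    if not math.isfinite(v):
        raise AapError(f"cannot bin non-finite activity value {v}")
    if v < BIN_LOW:
        return 0
    if v > BIN_HIGH:
        return N_BINS - 1
    idx = 1 + int((v - BIN_LOW) / BIN_WIDTH + _EDGE_EPS)
    return min(idx, N_REGULAR_BINS)


@dataclass
class Template:
    """Per-descriptor mu/sigma profile of one (cell line, activity bin)."""

    cell_line: str
    bin: ActivityBin
    member_count: int
    mu: np.ndarray      # NaN where no member has the descriptor
    sigma: np.ndarray   # floored; NaN where mu is NaN

    def equals(self, other: "Template") -> bool:
        return (
            self.cell_line == other.cell_line
            and self.bin == other.bin
            and self.member_count == other.member_count
            and np.array_equal(self.mu, other.mu, equal_nan=True)
            and np.array_equal(self.sigma, other.sigma, equal_nan=True)
        )


@dataclass
class TemplateSet:
    """All 42 templates for every modelled cell line, plus selection state."""

    descriptor_list: list[str]
    templates: dict[str, list[Template]]       # cell line -> 42 templates
    selected: dict[str, list[str]]             # cell line -> top-N descriptor names
    min_members: int = 1
    _stacks: dict[str, tuple] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cl, ts in self.templates.items():
            if len(ts) != N_BINS:
                raise AapError(
                    f"cell line {cl!r} has {len(ts)} templates, expected {N_BINS}"
                )

    @property
    def cell_lines(self) -> list[str]:
        return list(self.templates)

    def member_total(self, cell_line: str) -> int:
        return sum(t.member_count for t in self.templates[cell_line])

    def active_templates(self, cell_line: str) -> list[Template]:
        """Templates eligible for matching (enough members)."""
        return [
            t for t in self.templates[cell_line] if t.member_count >= self.min_members
        ]

    def _stack(self, cell_line: str):
        """Cache (mu matrix, sigma matrix, bin idx, counts, sel idx) per line."""
        if cell_line not in self._stacks:
            active = self.active_templates(cell_line)
            name_to_col = {n: k for k, n in enumerate(self.descriptor_list)}
            sel_idx = np.array(
                [name_to_col[n] for n in self.selected[cell_line]], dtype=int
            )
            if active:
                mu = np.vstack([t.mu[sel_idx] for t in active])
                sigma = np.vstack([t.sigma[sel_idx] for t in active])
            else:
                mu = np.empty((0, len(sel_idx)))
                sigma = np.empty((0, len(sel_idx)))
            bins = np.array([t.bin.index for t in active], dtype=int)
            counts = np.array([t.member_count for t in active], dtype=int)
            self._stacks[cell_line] = (mu, sigma, bins, counts, sel_idx)
        return self._stacks[cell_line]

    def equals(self, other: "TemplateSet") -> bool:
        if (
            self.descriptor_list != other.descriptor_list
            or self.selected != other.selected
            or self.min_members != other.min_members
            or list(self.templates) != list(other.templates)
        ):
            return False
        return all(
            a.equals(b)
            for cl in self.templates
            for a, b in zip(self.templates[cl], other.templates[cl])
        )


def _floor_sigma(sigma: np.ndarray, mu: np.ndarray) -> np.ndarray:
    floor = SIGMA_FLOOR_REL * np.maximum(np.abs(mu), 1.0)
    return np.where(np.isnan(sigma), np.nan, np.maximum(sigma, floor))


def build_templates(
    desc: DescriptorMatrix,
    act: ActivityMatrix,
    params: CLParams,
    min_members: int = 1,
) -> TemplateSet:
    """Build the per-cell-line activity-bin templates from training data.

    ``desc`` should already be zero-filtered and row-aligned with ``act``.
    Per (cell line, bin), mu and sigma (population, floored) are computed per
    descriptor over member compounds' observed values; empty templates are
    retained with member_count 0.  Cell lines with no observed activity at
    all are excluded with a warning.  Finally the top-N descriptors are
    selected per cell line so template scores within a line are comparable.
    """
    if desc.row_ids != act.row_ids:
        raise AapError("descriptor and activity matrices are not row-aligned")
    # canonical member order (by compound id) makes the mu/sigma floating-point
    # sums, hence the whole TemplateSet, invariant under input row permutation
    order = np.argsort(np.asarray(desc.row_ids, dtype=object))
    dvals = desc.values.to_numpy()[order]
    templates: dict[str, list[Template]] = {}
    selected: dict[str, list[str]] = {}
    for cl in act.col_ids:
        col = act.values[cl].to_numpy()[order]
        observed = ~np.isnan(col)
        if observed.sum() == 0:
            logger.warning(
                "cell line %r has no activity data and is excluded from the model",
                cl,
            )
            continue
        bin_idx = np.full(len(col), -1, dtype=int)
        bin_idx[observed] = [assign_bin(v) for v in col[observed]]
        ts: list[Template] = []
        for b in range(N_BINS):
            members = dvals[bin_idx == b]
            n = members.shape[0]
            if n == 0:
                mu = np.full(dvals.shape[1], np.nan)
                sigma = np.full(dvals.shape[1], np.nan)
            else:
                # population mu/sigma over observed member values; all-missing
                # descriptor columns stay NaN (nanmean warns on empty slices)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    mu = np.nanmean(members, axis=0)
                    sigma = np.nanstd(members, axis=0, ddof=0)
                sigma = _floor_sigma(sigma, mu)
            ts.append(Template(cl, ALL_BINS[b], int(n), mu, sigma))
        templates[cl] = ts
        non_empty = [t for t in ts if t.member_count >= min_members]
        selected[cl] = select_top_descriptors(desc, non_empty, params.N)
    if not templates:
        raise AapError("no cell line has any activity data; cannot build templates")
    return TemplateSet(
        descriptor_list=desc.col_ids,
        templates=templates,
        selected=selected,
        min_members=min_members,
    )


def _kernel(z2: np.ndarray, mode: str) -> np.ndarray:
    if mode == "b":
        return np.exp(-z2 / 2.0)
    if mode == "c":
        return np.exp(-z2 / 8.0)
    raise AapError(f"unknown smoothing mode {mode!r}")


def template_match_score(
    query_vec: np.ndarray,
    template: Template,
    selected_descriptors: Sequence[str],
    descriptor_list: Sequence[str],
    G: str = "a",
) -> float | None:
    """Score one query against one template over the selected descriptors.

    Returns the mean per-descriptor contribution over usable positions
    (query observed and template defined), or None when no position is
    usable or the template is empty.
    """
    if template.member_count == 0:
        return None
    name_to_col = {n: k for k, n in enumerate(descriptor_list)}
    idx = np.array([name_to_col[n] for n in selected_descriptors], dtype=int)
    q = np.asarray(query_vec, dtype=float)[idx]
    mu = template.mu[idx]
    sigma = template.sigma[idx]
    usable = ~np.isnan(q) & ~np.isnan(mu)
    if not usable.any():
        return None
    q, mu, sigma = q[usable], mu[usable], sigma[usable]
    if G == "a":
        contrib = (np.abs(q - mu) <= sigma).astype(float)
    else:
        z2 = ((q - mu) / sigma) ** 2
        contrib = _kernel(z2, G)
    return float(contrib.mean())


def cl_predict(
    query_vec: np.ndarray,
    template_set: TemplateSet,
    params: CLParams,
) -> dict[str, tuple[float, int, float]]:
    """Assign per cell line the activity of the best-matching template.

    Returns ``{cell_line: (gi50_cl, winning bin index, winning score)}``.
    Ties on the score prefer the template with more members, then the lower
    bin index.  Cell lines where no template is usable are omitted (the
    caller records them as missing).
    """
    q_full = np.asarray(query_vec, dtype=float)
    if q_full.shape[0] != len(template_set.descriptor_list):
        raise AapError(
            f"query vector length {q_full.shape[0]} does not match the "
            f"{len(template_set.descriptor_list)}-descriptor template set"
        )
    out: dict[str, tuple[float, int, float]] = {}
    for cl in template_set.cell_lines:
        mu, sigma, bins, counts, sel_idx = template_set._stack(cl)
        if mu.shape[0] == 0:
            logger.warning("cell line %r has no usable template; skipping", cl)
            continue
        q = q_full[sel_idx]
        usable = ~np.isnan(q)[None, :] & ~np.isnan(mu)
        n_usable = usable.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            if params.G == "a":
                contrib = (np.abs(q[None, :] - mu) <= sigma).astype(float)
            else:
                z2 = ((q[None, :] - mu) / sigma) ** 2
                contrib = _kernel(z2, params.G)
            contrib = np.where(usable, contrib, 0.0)
            scores = np.where(
                n_usable > 0, contrib.sum(axis=1) / np.maximum(n_usable, 1), -np.inf
            )
        if np.all(scores == -np.inf):
            logger.warning(
                "query shares no descriptor with any template of cell line %r", cl
            )
            continue
        # argmax with deterministic tie-break: score, then members, then low bin
        order = sorted(
            range(len(scores)),
            key=lambda k: (-scores[k], -counts[k], bins[k]),
        )
        best = order[0]
        out[cl] = (
            ALL_BINS[bins[best]].assigned_value,
            int(bins[best]),
            float(scores[best]),
        )
    return out


# ---------------------------------------------------------------------------
# audit table import/export
# ---------------------------------------------------------------------------


def export_template_table(template_set: TemplateSet) -> pd.DataFrame:
    """Long-form audit table of every template's statistics.

    Columns: cell_line, bin_index, lower, upper, assigned_value,
    member_count, descriptor, mu, sigma.  Empty templates appear once with an
    empty descriptor field so member counts stay auditable.
    """
    rows = []
    for cl in template_set.cell_lines:
        for t in template_set.templates[cl]:
            base = {
                "cell_line": cl,
                "bin_index": t.bin.index,
                "lower": t.bin.lower,
                "upper": t.bin.upper,
                "assigned_value": t.bin.assigned_value,
                "member_count": t.member_count,
            }
            if t.member_count == 0:
                rows.append({**base, "descriptor": np.nan, "mu": np.nan, "sigma": np.nan})
                continue
            for k, name in enumerate(template_set.descriptor_list):
                rows.append(
                    {**base, "descriptor": name, "mu": t.mu[k], "sigma": t.sigma[k]}
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_line", "bin_index", "lower", "upper", "assigned_value",
            "member_count", "descriptor", "mu", "sigma",
        ],
    )


def template_set_from_table(
    table: pd.DataFrame,
    descriptor_list: Sequence[str],
    cell_lines: Sequence[str],
    selected: Mapping[str, Sequence[str]],
    min_members: int = 1,
) -> TemplateSet:
    """Rebuild a TemplateSet from the audit table written by export."""
    d = len(descriptor_list)
    name_to_col = {n: k for k, n in enumerate(descriptor_list)}
    templates: dict[str, list[Template]] = {}
    grouped = {
        (str(cl), int(b)): g
        for (cl, b), g in table.groupby(["cell_line", "bin_index"], sort=False)
    }
    for cl in cell_lines:
        ts = []
        for b in range(N_BINS):
            g = grouped.get((cl, b))
            if g is None:
                raise AapError(f"template table lacks bin {b} of cell line {cl!r}")
            count = int(g["member_count"].iloc[0])
            mu = np.full(d, np.nan)
            sigma = np.full(d, np.nan)
            if count > 0:
                for _, r in g.iterrows():
                    if isinstance(r["descriptor"], str):
                        k = name_to_col[r["descriptor"]]
                        mu[k] = r["mu"]
                        sigma[k] = r["sigma"]
            ts.append(Template(cl, ALL_BINS[b], count, mu, sigma))
        templates[cl] = ts
    return TemplateSet(
        descriptor_list=list(descriptor_list),
        templates=templates,
        selected={cl: list(v) for cl, v in selected.items()},
        min_members=min_members,
    )
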