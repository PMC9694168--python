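"""Core data containers and file I/O for the antiproliferative-activity predictor.

The predictor works on two aligned matrices:

* a **descriptor matrix** — compounds x molecular descriptors, real-valued,
  with missing entries allowed (a descriptor the backend could not compute);
* an **activity matrix** — compounds x cell lines of -log10(GI50 / M)
  ("pGI50") values from a growth-inhibition panel, with missing entries for
  (compound, cell line) pairs that were never assayed, plus a mapping from
  each cell line to its tumour-type subpanel.

Missing values are represented as NaN in memory and as an empty field (or
"NA") on disk.  Compound and cell-line identifiers are opaque strings: NSC
codes such as "0123" keep their leading zeros.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .descriptors import CLParams
    from .templates import TemplateSet

logger = logging.getLogger("aap")

#: Serialization layout version written into every model manifest.
MODEL_FORMAT_VERSION = 1

#: Strings accepted as a missing value when reading delimited text.
NA_STRINGS = ("", "NA")


class AapError(ValueError):
    """Raised for malformed inputs or contract violations."""


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureRecord:
    """One input chemical structure.

    Parameters
    ----------
    id:
        Opaque compound identifier (e.g. an NSC code).  Must be non-empty and
        unique within a collection.
    structure:
        The raw structural payload: an MDL mol block for SDF input, or a
        SMILES string.  Descriptor backends re-parse this payload.
    fmt:
        ``"sdf"`` or ``"smiles"`` — how to interpret ``structure``.
    name:
        Optional human-readable label.
    """

    id: str
    structure: str
    fmt: str = "smiles"
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise AapError("structure record has an empty id")
        if self.fmt not in ("sdf", "smiles"):
            raise AapError(f"unknown structure format {self.fmt!r}")


def read_structures(
    path: str | Path,
    format: str,
    id_property: str | None = None,
) -> list[StructureRecord]:
    """Read chemical structures from an SDF (V2000) or SMILES file.

    For SDF input the compound id is taken from the SDF property named by
    ``id_property``, or from the molecule title line when ``id_property`` is
    None.  For SMILES input each non-empty line is ``<smiles> <id>``
    (whitespace separated); the second column is mandatory.

    Record order is preserved.  An unparsable record or a duplicate id raises
    :class:`AapError` naming the offending record.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    path = Path(path)
    if not path.exists():
        raise AapError(f"structure file not found: {path}")
    records: list[StructureRecord] = []
    seen: set[str] = set()

    def add(rec: StructureRecord, index: int) -> None:
        if rec.id in seen:
            raise AapError(f"duplicate compound id {rec.id!r} at record {index}")
        seen.add(rec.id)
        records.append(rec)

    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise AapError(f"unparsable SDF record at index {i} in {path}")
            if id_property is not None:
                if not mol.HasProp(id_property):
                    raise AapError(
                        f"SDF record {i} lacks the id property {id_property!r}"
                    )
                cid = mol.GetProp(id_property).strip()
            else:
                cid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            if not cid:
                raise AapError(f"SDF record {i} has an empty id")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else None
            add(
                StructureRecord(
                    id=cid, structure=Chem.MolToMolBlock(mol), fmt="sdf", name=name
                ),
                i,
            )
    elif format == "smiles":
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise AapError(
                        f"SMILES line {i + 1} lacks an id column: {line!r}"
                    )
                smiles, cid = parts[0], parts[1]
                if Chem.MolFromSmiles(smiles) is None:
                    raise AapError(
                        f"unparsable SMILES at line {i + 1}: {smiles!r}"
                    )
                add(StructureRecord(id=cid, structure=smiles, fmt="smiles"), i)
    else:
        raise AapError(f"unknown structure format {format!r} (use 'sdf' or 'smiles')")
    return records


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def _clean_frame(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Coerce to float64, map infinities to NaN, enforce unique axes."""
    if df.shape[1] < 1:
        raise AapError(f"{what} must have at least one column")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise AapError(f"duplicate row id {dup!r} in {what}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise AapError(f"duplicate column id {dup!r} in {what}")
    df = df.astype(np.float64)
    df = df.replace([np.inf, -np.inf], np.nan)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors matrix; NaN marks a missing descriptor value."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = _clean_frame(self.values, "descriptor matrix")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_arrays(
        cls,
        row_ids: Sequence[str],
        col_ids: Sequence[str],
        values: np.ndarray,
    ) -> "DescriptorMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(row_ids), columns=list(col_ids)))

    def row(self, compound_id: str) -> np.ndarray:
        return self.values.loc[compound_id].to_numpy()

    def subset_rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise AapError(f"unknown compound ids: {missing}")
        return DescriptorMatrix(self.values.loc[list(ids)])

    def subset_cols(self, cols: Sequence[str]) -> "DescriptorMatrix":
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise AapError(f"unknown descriptor columns: {missing}")
        return DescriptorMatrix(self.values[list(cols)])

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="compound_id", na_rep="")

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(
            path, index_col=0, dtype={0: str},
            na_values=list(NA_STRINGS), keep_default_na=False,
            float_precision="round_trip",
        )
        df.index = df.index.astype(str)
        return cls(df)

    def equals(self, other: "DescriptorMatrix") -> bool:
        return self.values.equals(other.values)


@dataclass
class ActivityMatrix:
    """Compounds x cell lines pGI50 matrix with a cell-line -> subpanel map.

    Values are -log10 of the molar GI50; the assay effectively spans ~4
    (inactive at 100 uM) to ~8 (active at 10 nM), but values outside [4, 8]
    are legal — they feed the underflow/overflow activity bins.
    """

    values: pd.DataFrame
    panel_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = _clean_frame(self.values, "activity matrix")
        self.panel_of = {str(k): str(v) for k, v in self.panel_of.items()}
        unassigned = [c for c in self.values.columns if c not in self.panel_of]
        if unassigned:
            raise AapError(f"cell lines without a panel assignment: {unassigned}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    def row(self, compound_id: str) -> pd.Series:
        return self.values.loc[compound_id]

    def n_observed(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def subset_rows(self, ids: Sequence[str]) -> "ActivityMatrix":
        missing = [i for i in ids if i not in self.values.index]
        if missing:
            raise AapError(f"unknown compound ids: {missing}")
        return ActivityMatrix(self.values.loc[list(ids)], dict(self.panel_of))

    def drop_cell_lines(self, cell_lines: Iterable[str]) -> "ActivityMatrix":
        keep = [c for c in self.values.columns if c not in set(cell_lines)]
        return ActivityMatrix(
            self.values[keep], {c: self.panel_of[c] for c in keep}
        )

    def to_long(self) -> pd.DataFrame:
        """Long-form view: one row per observed (compound, cell line) pair."""
        long = self.values.stack().rename("pGI50").reset_index()
        long.columns = ["compound_id", "cell_line", "pGI50"]
        long["panel"] = long["cell_line"].map(self.panel_of)
        return long[["compound_id", "cell_line", "panel", "pGI50"]]

    def equals(self, other: "ActivityMatrix") -> bool:
        return self.values.equals(other.values) and self.panel_of == other.panel_of


def read_activity_table(
    path: str | Path,
    layout: str = "long",
    panel_path: str | Path | None = None,
) -> ActivityMatrix:
    """Read a pGI50 activity table from delimited text (comma or tab).

    ``layout="long"`` expects columns ``compound_id, cell_line, panel, pGI50``
    (one observed pair per row; absent pairs become missing).  ``layout="wide"``
    expects a ``compound_id`` column plus one column per cell line, and a side
    file ``panel_path`` with columns ``cell_line, panel``.

    The reader stores values verbatim — any GI50 -> pGI50 conversion is the
    caller's job.  Duplicate (compound, cell line) pairs and non-numeric
    activity values are rejected.
    """
    path = Path(path)
    if layout == "long":
        df = pd.read_csv(
            path, sep=None, engine="python", dtype=str,
            na_values=list(NA_STRINGS), keep_default_na=False,
        )
        required = ["compound_id", "cell_line", "panel", "pGI50"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise AapError(f"long activity table lacks columns {missing_cols}")
        vals = pd.to_numeric(df["pGI50"], errors="coerce")
        bad = df.index[df["pGI50"].notna() & vals.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise AapError(
                f"non-numeric pGI50 at data row {bad[0] + 2}: {df['pGI50'][bad[0]]!r}"
            )
        if df["panel"].isna().any():
            row = int(df.index[df["panel"].isna()][0])
            raise AapError(f"missing panel at data row {row + 2}")
        dup = df.duplicated(subset=["compound_id", "cell_line"])
        if dup.any():
            r = df[dup].iloc[0]
            raise AapError(
                f"duplicate (compound, cell line) pair ({r['compound_id']}, {r['cell_line']})"
            )
        conflict = df.groupby("cell_line")["panel"].nunique()
        if (conflict > 1).any():
            cl = conflict[conflict > 1].index[0]
            raise AapError(f"cell line {cl!r} assigned to more than one panel")
        df = df.assign(pGI50=vals)
        wide = df.pivot(index="compound_id", columns="cell_line", values="pGI50")
        # preserve first-appearance order of compounds and cell lines
        wide = wide.reindex(index=pd.unique(df["compound_id"]),
                            columns=pd.unique(df["cell_line"]))
        panel_of = dict(zip(df["cell_line"], df["panel"]))
        return ActivityMatrix(wide, panel_of)
    if layout == "wide":
        if panel_path is None:
            raise AapError("wide layout requires a panel side file (panel_path)")
        # the delimiter-sniffing python engine converts via float(), which is
        # already correctly rounded, so no float_precision option is needed
        df = pd.read_csv(
            path, sep=None, engine="python", index_col="compound_id",
            na_values=list(NA_STRINGS), keep_default_na=False,
        )
        df.index = df.index.astype(str)
        panels = pd.read_csv(panel_path, sep=None, engine="python", dtype=str)
        if not {"cell_line", "panel"} <= set(panels.columns):
            raise AapError("panel file must have columns cell_line, panel")
        panel_of = dict(zip(panels["cell_line"], panels["panel"]))
        unknown = [c for c in df.columns if c not in panel_of]
        if unknown:
            raise AapError(f"cell lines missing from panel file: {unknown}")
        try:
            df = df.astype(np.float64)
        except ValueError as exc:
            raise AapError(f"non-numeric activity value in {path}: {exc}") from exc
        return ActivityMatrix(df, {c: panel_of[c] for c in df.columns})
    raise AapError(f"unknown activity layout {layout!r} (use 'long' or 'wide')")


def write_activity_table(act: ActivityMatrix, path: str | Path) -> None:
    """Write an activity matrix in the canonical long layout."""
    act.to_long().to_csv(path, index=False, na_rep="")


def split_by_membership(
    activity: ActivityMatrix, training_ids: Sequence[str]
) -> tuple[ActivityMatrix, ActivityMatrix]:
    """Partition compounds into a training and a test activity matrix.

    Row sets are disjoint and jointly exhaustive; both halves keep the full
    cell-line column set (a test matrix may have zero rows).
    """
    ids = list(training_ids)
    unknown = [i for i in ids if i not in activity.values.index]
    if unknown:
        raise AapError(f"training ids not present in activity matrix: {unknown}")
    chosen = set(ids)
    test_ids = [i for i in activity.row_ids if i not in chosen]
    train = ActivityMatrix(activity.values.loc[ids], dict(activity.panel_of))
    test = ActivityMatrix(
        activity.values.loc[test_ids].reindex(columns=activity.values.columns),
        dict(activity.panel_of),
    )
    return train, test


# ---------------------------------------------------------------------------
# model bundle + serialization
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    """The trained state of the predictor, ready to score new compounds.

    Holds the (zero-filtered) training descriptor matrix used by the
    similarity module, the training activity matrix whose rows are
    transferred to queries, the per-cell-line activity-bin templates, the
    build parameters, and the cell lines excluded for lack of data.
    """

    descriptor_backend_id: str
    descriptor_list: list[str]
    training_descriptors: DescriptorMatrix
    training_activity: ActivityMatrix
    template_set: "TemplateSet"
    build_params: "CLParams"
    excluded_cell_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.descriptor_list != self.template_set.descriptor_list:
            raise AapError(
                "descriptor_list differs between training descriptors and templates"
            )
        bad = [c for c in self.excluded_cell_lines if c in self.template_set.cell_lines]
        if bad:
            raise AapError(f"excluded cell lines present in template set: {bad}")

    def equals(self, other: "ModelBundle") -> bool:
        return (
            self.descriptor_backend_id == other.descriptor_backend_id
            and self.descriptor_list == other.descriptor_list
            and self.training_descriptors.equals(other.training_descriptors)
            and self.training_activity.equals(other.training_activity)
            and self.template_set.equals(other.template_set)
            and self.build_params == other.build_params
            and self.excluded_cell_lines == other.excluded_cell_lines
        )


def save_model(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize a model bundle to a directory of delimited text + manifest.

    The layout is plain CSV/JSON so a saved model is diffable and portable;
    floats are written in shortest round-trip form, so load(save(b)) is
    bitwise-identical to b.
    """
    from .templates import export_template_table

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    p = bundle.build_params
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "descriptor_backend_id": bundle.descriptor_backend_id,
        "descriptor_list": bundle.descriptor_list,
        "build_params": {"N": p.N, "Z": p.Z, "G": p.G},
        "min_members": bundle.template_set.min_members,
        "excluded_cell_lines": bundle.excluded_cell_lines,
        "cell_lines": bundle.template_set.cell_lines,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle.training_descriptors.to_csv(path / "training_descriptors.csv")
    bundle.training_activity.values.to_csv(
        path / "training_activity.csv", index_label="compound_id", na_rep=""
    )
    pd.DataFrame(
        {
            "cell_line": list(bundle.training_activity.panel_of),
            "panel": list(bundle.training_activity.panel_of.values()),
        }
    ).to_csv(path / "panels.csv", index=False)
    export_template_table(bundle.template_set).to_csv(
        path / "templates.csv", index=False, na_rep=""
    )
    sel_rows = []
    for cl in bundle.template_set.cell_lines:
        for rank, name in enumerate(bundle.template_set.selected[cl]):
            sel_rows.append({"cell_line": cl, "rank": rank, "descriptor": name})
    pd.DataFrame(sel_rows, columns=["cell_line", "rank", "descriptor"]).to_csv(
        path / "selected_descriptors.csv", index=False
    )


def load_model(path: str | Path) -> ModelBundle:
    """Load a model bundle saved by :func:`save_model`."""
    from .descriptors import CLParams
    from .templates import TemplateSet, template_set_from_table

    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise AapError(f"not a model directory (no manifest.json): {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise AapError(f"corrupted model manifest in {path}: {exc}") from exc
    version = manifest.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise AapError(
            f"model format version mismatch: expected {MODEL_FORMAT_VERSION}, "
            f"found {version}"
        )
    desc = DescriptorMatrix.read_csv(path / "training_descriptors.csv")
    act_df = pd.read_csv(
        path / "training_activity.csv", index_col="compound_id",
        na_values=list(NA_STRINGS), keep_default_na=False,
        float_precision="round_trip",
    )
    act_df.index = act_df.index.astype(str)
    panels = pd.read_csv(path / "panels.csv", dtype=str)
    panel_of = dict(zip(panels["cell_line"], panels["panel"]))
    act = ActivityMatrix(act_df, panel_of)
    table = pd.read_csv(
        path / "templates.csv",
        na_values=list(NA_STRINGS), keep_default_na=False,
        float_precision="round_trip", dtype={"cell_line": str, "descriptor": str},
    )
    sel = pd.read_csv(path / "selected_descriptors.csv", dtype={"cell_line": str})
    selected: dict[str, list[str]] = {}
    for cl, grp in sel.groupby("cell_line", sort=False):
        selected[str(cl)] = list(grp.sort_values("rank")["descriptor"])
    template_set = template_set_from_table(
        table,
        descriptor_list=list(manifest["descriptor_list"]),
        cell_lines=list(manifest["cell_lines"]),
        selected=selected,
        min_members=int(manifest["min_members"]),
    )
    params = CLParams(**manifest["build_params"])
    return ModelBundle(
        descriptor_backend_id=manifest["descriptor_backend_id"],
        descriptor_list=list(manifest["descriptor_list"]),
        training_descriptors=desc,
        training_activity=act,
        template_set=template_set,
        build_params=params,
        excluded_cell_lines=list(manifest["excluded_cell_lines"]),
    )
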