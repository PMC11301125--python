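"""Core data containers and delimited-text I/O.

Three containers back the whole pipeline:

* :class:`ResponseMatrix` — respondent x item binary responses with a group
  label and patient identifier per row.  Missing responses are held as
  ``pd.NA`` in a nullable integer frame, never as a numeric sentinel.
* :class:`ItemBank` — per-item two-parameter-logistic parameters
  (discrimination ``a``, severity ``b``) for a reference and a focal group,
  with a shared/group-specific constraint per parameter and an anchor set.
* :class:`LatentDistribution` — per-group latent trait moments with the
  reference group fixed at mean 0, variance 1.

File formats are plain UTF-8 delimited text (comma by default).  Response
files carry one row per checklist with columns ``patient_id``, ``group`` and
one column per item; empty cells and ``NA`` mean missing.  Item-bank files
are long-format with columns ``item_id, group, a, b, anchor``: a ``shared``
(or reference-group) row gives the pooled parameters, and an optional
focal-group row overrides the parameters that are group-specific — a dash or
empty cell in that row means "shared", mirroring how published DIF parameter
tables print dashes for equality-constrained entries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger("audcheck")

#: tokens accepted as "missing" in response files
MISSING_TOKENS = frozenset({"", "NA", "na", "NaN", "nan"})
#: tokens accepted as "shared with the reference group" in item-bank files
SHARED_TOKENS = frozenset({"", "-", "—", "NA", "na"})


# ---------------------------------------------------------------------------
# ResponseMatrix


@dataclass
class ResponseMatrix:
    """Binary item responses with one group label and patient id per row."""

    patient_id: np.ndarray
    group: np.ndarray
    responses: pd.DataFrame  # nullable Int8, one column per item

    def __post_init__(self) -> None:
        self.patient_id = np.asarray(self.patient_id, dtype=object)
        self.group = np.asarray(self.group, dtype=object)
        if not (len(self.patient_id) == len(self.group) == len(self.responses)):
            raise ValidationError("patient_id, group and responses disagree on row count")
        self.responses = self.responses.astype("Int8")
        vals = self.responses.to_numpy(dtype="float64", na_value=np.nan)
        bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary response at row {r}, item {self.responses.columns[c]!r}"
            )
        if len(self.groups) > 2:
            raise ValidationError(f"more than two groups present: {self.groups}")
        self.responses.index = pd.RangeIndex(len(self.responses))

    # -- properties ---------------------------------------------------------
    @property
    def item_ids(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_respondents(self) -> int:
        return len(self.responses)

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.group == g).sum()) for g in self.groups}

    @property
    def is_complete(self) -> bool:
        return not self.responses.isna().to_numpy().any()

    def complete_values(self) -> np.ndarray:
        """Responses as an ``(n, J)`` uint8 array; raises if anything is missing."""
        if not self.is_complete:
            raise ValidationError(
                "response matrix contains missing items; run filter_complete first"
            )
        return self.responses.to_numpy(dtype="uint8")

    def subset(self, mask: np.ndarray) -> "ResponseMatrix":
        mask = np.asarray(mask)
        return ResponseMatrix(
            self.patient_id[mask],
            self.group[mask],
            self.responses.loc[mask].reset_index(drop=True),
        )

    def reorder_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        missing = set(item_ids) - set(self.item_ids)
        if missing:
            raise ValidationError(f"items not present in matrix: {sorted(missing)}")
        return ResponseMatrix(self.patient_id, self.group, self.responses[list(item_ids)])

    def __eq__(self, other: object) -> bool:  # row-order sensitive
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return (
            list(self.patient_id) == list(other.patient_id)
            and list(self.group) == list(other.group)
            and self.item_ids == other.item_ids
            and self.responses.equals(other.responses)
        )


def read_responses(
    path: str | Path,
    *,
    patient_col: str = "patient_id",
    group_col: str = "group",
    item_cols: Sequence[str] | None = None,
    delimiter: str = ",",
) -> ResponseMatrix:
    """Read a delimited response file into a validated :class:`ResponseMatrix`.

    ``item_cols`` names (and orders) the item columns; when omitted every
    column other than ``patient_col`` and ``group_col`` is treated as an item,
    in file order.  Cells must parse to 0, 1 or a missing token.
    """
    raw = pd.read_csv(path, dtype=str, sep=delimiter, keep_default_na=False)
    for col in (patient_col, group_col):
        if col not in raw.columns:
            raise ParseError(f"{path}: required column {col!r} not found")
    if item_cols is None:
        item_cols = [c for c in raw.columns if c not in (patient_col, group_col)]
    else:
        absent = [c for c in item_cols if c not in raw.columns]
        if absent:
            raise ParseError(f"{path}: item columns not found: {absent}")

    parsed = {}
    for col in item_cols:
        out = np.empty(len(raw), dtype=object)
        for i, v in enumerate(raw[col].to_numpy()):
            v = v.strip()
            if v in MISSING_TOKENS:
                out[i] = pd.NA
            elif v in ("0", "1"):
                out[i] = int(v)
            else:
                raise ParseError(
                    f"{path}: row {i + 2}, column {col!r}: cannot parse {v!r} as 0/1/NA"
                )
        parsed[col] = pd.array(out, dtype="Int8")

    groups = [g for g in raw[group_col].str.strip().unique() if g != ""]
    if len(groups) > 2:
        raise ValidationError(f"{path}: more than two groups present: {sorted(groups)}")
    data = ResponseMatrix(
        raw[patient_col].to_numpy(dtype=object),
        raw[group_col].str.strip().to_numpy(dtype=object),
        pd.DataFrame(parsed, columns=list(item_cols)),
    )
    logger.info(
        "read %d checklists (%s) from %s",
        data.n_respondents,
        ", ".join(f"{g}: n={n}" for g, n in data.group_sizes().items()),
        path,
    )
    return data


def write_responses(data: ResponseMatrix, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a response matrix as delimited text; missing responses become empty cells."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["patient_id", "group"] + data.item_ids)
        vals = data.responses.to_numpy(dtype=object)
        for pid, grp, row in zip(data.patient_id, data.group, vals):
            writer.writerow(
                [pid, grp] + ["" if v is pd.NA or v is None else int(v) for v in row]
            )


def filter_complete(data: ResponseMatrix) -> tuple[ResponseMatrix, dict[str, int]]:
    """Drop checklists with any missing item; report exclusions per group."""
    complete = ~data.responses.isna().any(axis=1).to_numpy()
    excluded = {
        g: int(((data.group == g) & ~complete).sum()) for g in data.groups
    }
    kept = data.subset(complete)
    logger.info(
        "excluded %d incomplete checklists (%s); %d retained",
        int((~complete).sum()),
        ", ".join(f"{g}: {n}" for g, n in excluded.items()),
        kept.n_respondents,
    )
    return kept, excluded


def select_one_per_patient(data: ResponseMatrix, seed: int) -> ResponseMatrix:
    """Keep exactly one checklist per patient, chosen uniformly at random.

    Deterministic for a fixed ``seed``; surviving rows keep their original
    relative order.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[object, list[int]] = {}
    for i, pid in enumerate(data.patient_id):
        by_patient.setdefault(pid, []).append(i)
    chosen = sorted(
        rows[rng.integers(len(rows))] if len(rows) > 1 else rows[0]
        for rows in by_patient.values()
    )
    mask = np.zeros(data.n_respondents, dtype=bool)
    mask[chosen] = True
    out = data.subset(mask)
    logger.info(
        "selected one checklist per patient: %d of %d rows retained",
        out.n_respondents,
        data.n_respondents,
    )
    return out


# ---------------------------------------------------------------------------
# ItemBank


@dataclass
class ItemBank:
    """2PL item parameters for a reference and focal group with equality constraints.

    ``a`` and ``b`` are ``(J, 2)`` arrays with column 0 the reference group
    and column 1 the focal group.  ``share_a[j]`` / ``share_b[j]`` mark the
    parameter as pooled across groups (the focal column then mirrors the
    reference column).  Anchor items are always fully shared.
    """

    item_ids: list[str]
    a: np.ndarray
    b: np.ndarray
    share_a: np.ndarray
    share_b: np.ndarray
    reference_group: str = "reference"
    focal_group: str = "focal"
    anchors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.item_ids = list(self.item_ids)
        J = len(self.item_ids)
        self.a = np.array(self.a, dtype=float).reshape(J, -1)
        self.b = np.array(self.b, dtype=float).reshape(J, -1)
        if self.a.shape[1] == 1:
            self.a = np.repeat(self.a, 2, axis=1)
        if self.b.shape[1] == 1:
            self.b = np.repeat(self.b, 2, axis=1)
        self.share_a = np.array(self.share_a, dtype=bool).reshape(J)
        self.share_b = np.array(self.share_b, dtype=bool).reshape(J)
        self.anchors = tuple(self.anchors)
        # enforce the shared convention: focal column mirrors reference
        self.a[self.share_a, 1] = self.a[self.share_a, 0]
        self.b[self.share_b, 1] = self.b[self.share_b, 0]
        if (self.a <= 0).any():
            j = int(np.argwhere(self.a <= 0)[0][0])
            raise ValidationError(
                f"discrimination must be positive; item {self.item_ids[j]!r} has a <= 0"
            )
        unknown = set(self.anchors) - set(self.item_ids)
        if unknown:
            raise ValidationError(f"anchor items not in bank: {sorted(unknown)}")
        idx = {item: j for j, item in enumerate(self.item_ids)}
        for item in self.anchors:
            j = idx[item]
            if not (self.share_a[j] and self.share_b[j]):
                raise ValidationError(
                    f"anchor item {item!r} must have both parameters shared"
                )

    # -- construction -------------------------------------------------------
    @classmethod
    def from_reference(
        cls,
        item_ids: Sequence[str],
        a: Sequence[float],
        b: Sequence[float],
        *,
        focal_a: Mapping[str, float] | None = None,
        focal_b: Mapping[str, float] | None = None,
        anchors: Sequence[str] = (),
        reference_group: str = "reference",
        focal_group: str = "focal",
    ) -> "ItemBank":
        """Build a bank from reference parameters plus focal-group overrides.

        Items absent from ``focal_a`` / ``focal_b`` keep the parameter shared
        across groups — the dash convention of published DIF tables.
        """
        item_ids = list(item_ids)
        focal_a = dict(focal_a or {})
        focal_b = dict(focal_b or {})
        J = len(item_ids)
        aa = np.column_stack([a, a]).astype(float)
        bb = np.column_stack([b, b]).astype(float)
        share_a = np.ones(J, dtype=bool)
        share_b = np.ones(J, dtype=bool)
        for item, val in focal_a.items():
            j = item_ids.index(item)
            aa[j, 1] = val
            share_a[j] = False
        for item, val in focal_b.items():
            j = item_ids.index(item)
            bb[j, 1] = val
            share_b[j] = False
        return cls(
            item_ids, aa, bb, share_a, share_b,
            reference_group=reference_group, focal_group=focal_group,
            anchors=tuple(anchors),
        )

    # -- access -------------------------------------------------------------
    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def groups(self) -> list[str]:
        return [self.reference_group, self.focal_group]

    def group_index(self, group: str) -> int:
        if group == self.reference_group:
            return 0
        if group == self.focal_group:
            return 1
        raise ValidationError(
            f"unknown group {group!r}; bank has {self.groups}"
        )

    def resolve(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-item ``(a, b)`` vectors for one group, shared entries resolved."""
        g = self.group_index(group)
        return self.a[:, g].copy(), self.b[:, g].copy()

    def is_anchor(self, item: str) -> bool:
        return item in self.anchors

    def all_shared(self) -> bool:
        return bool(self.share_a.all() and self.share_b.all())

    def to_frame(self) -> pd.DataFrame:
        """Wide per-item table; focal entries are NaN where shared."""
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "a_reference": self.a[:, 0],
                "b_reference": self.b[:, 0],
                "a_focal": np.where(self.share_a, np.nan, self.a[:, 1]),
                "b_focal": np.where(self.share_b, np.nan, self.b[:, 1]),
                "anchor": [it in self.anchors for it in self.item_ids],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItemBank):
            return NotImplemented
        return (
            self.item_ids == other.item_ids
            and np.array_equal(self.a, other.a)
            and np.array_equal(self.b, other.b)
            and np.array_equal(self.share_a, other.share_a)
            and np.array_equal(self.share_b, other.share_b)
            and self.anchors == other.anchors
            and self.reference_group == other.reference_group
            and self.focal_group == other.focal_group
        )


def write_item_bank(bank: ItemBank, path: str | Path, *, delimiter: str = ",") -> None:
    """Serialize a bank as long-format delimited text.

    One reference-group row per item; a focal-group row only for items with
    any group-specific parameter, with empty cells for the still-shared
    parameter.  Floats round-trip exactly (written with ``repr``).
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["item_id", "group", "a", "b", "anchor"])
        for j, item in enumerate(bank.item_ids):
            writer.writerow(
                [item, bank.reference_group, repr(float(bank.a[j, 0])),
                 repr(float(bank.b[j, 0])), int(item in bank.anchors)]
            )
            if not (bank.share_a[j] and bank.share_b[j]):
                writer.writerow(
                    [
                        item,
                        bank.focal_group,
                        "" if bank.share_a[j] else repr(float(bank.a[j, 1])),
                        "" if bank.share_b[j] else repr(float(bank.b[j, 1])),
                        0,
                    ]
                )


def read_item_bank(
    path: str | Path,
    *,
    reference_group: str | None = None,
    focal_group: str | None = None,
    delimiter: str = ",",
) -> ItemBank:
    """Read a long-format item-bank file.

    Rows whose group is ``shared`` (or the reference group) define the pooled
    parameters; focal rows override only the cells that are present — dashes
    and empty cells mean "shared".  When group names are not passed they are
    taken in file order (first-seen non-shared group is the reference).
    """
    raw = pd.read_csv(path, dtype=str, sep=delimiter, keep_default_na=False)
    required = {"item_id", "group", "a", "b"}
    if not required.issubset(raw.columns):
        raise ParseError(f"{path}: item-bank file needs columns {sorted(required)}")

    file_groups = [g for g in raw["group"].str.strip().unique() if g.lower() != "shared"]
    if reference_group is None:
        reference_group = file_groups[0] if file_groups else "reference"
    if focal_group is None:
        others = [g for g in file_groups if g != reference_group]
        if len(others) > 1:
            raise ValidationError(f"{path}: more than two groups: {file_groups}")
        focal_group = others[0] if others else "focal"

    item_ids: list[str] = []
    ref_a: dict[str, float] = {}
    ref_b: dict[str, float] = {}
    focal_a: dict[str, float] = {}
    focal_b: dict[str, float] = {}
    anchors: list[str] = []

    def _num(cell: str, row: int, col: str) -> float:
        try:
            return float(cell)
        except ValueError:
            raise ParseError(f"{path}: row {row + 2}, column {col!r}: bad value {cell!r}")

    for i, rec in raw.iterrows():
        item = rec["item_id"].strip()
        group = rec["group"].strip()
        a_cell, b_cell = rec["a"].strip(), rec["b"].strip()
        anchor_cell = str(rec.get("anchor", "0")).strip()
        if group.lower() == "shared" or group == reference_group:
            if item not in item_ids:
                item_ids.append(item)
            ref_a[item] = _num(a_cell, i, "a")
            ref_b[item] = _num(b_cell, i, "b")
            if anchor_cell not in ("", "0", "False", "false"):
                anchors.append(item)
        elif group == focal_group:
            if item not in item_ids:
                item_ids.append(item)
            if a_cell not in SHARED_TOKENS:
                focal_a[item] = _num(a_cell, i, "a")
            if b_cell not in SHARED_TOKENS:
                focal_b[item] = _num(b_cell, i, "b")
        else:
            raise ValidationError(f"{path}: row {i + 2}: unknown group {group!r}")

    missing_ref = [it for it in item_ids if it not in ref_a]
    if missing_ref:
        raise ParseError(f"{path}: no reference parameters for items {missing_ref}")
    bad_anchor = set(anchors) & (set(focal_a) | set(focal_b))
    if bad_anchor:
        raise ValidationError(
            f"{path}: anchor items cannot have group-specific parameters: {sorted(bad_anchor)}"
        )
    return ItemBank.from_reference(
        item_ids,
        [ref_a[i] for i in item_ids],
        [ref_b[i] for i in item_ids],
        focal_a=focal_a,
        focal_b=focal_b,
        anchors=anchors,
        reference_group=reference_group,
        focal_group=focal_group,
    )


# ---------------------------------------------------------------------------
# LatentDistribution


@dataclass
class LatentDistribution:
    """Per-group latent normal moments; the reference group is fixed at N(0, 1)."""

    means: dict[str, float] = field(default_factory=dict)
    variances: dict[str, float] = field(default_factory=dict)
    reference_group: str = "reference"

    def __post_init__(self) -> None:
        self.means = {g: float(m) for g, m in self.means.items()}
        self.variances = {g: float(v) for g, v in self.variances.items()}
        if self.reference_group not in self.means:
            self.means[self.reference_group] = 0.0
            self.variances[self.reference_group] = 1.0
        if self.means[self.reference_group] != 0.0 or self.variances[self.reference_group] != 1.0:
            raise ValidationError("reference group moments must be exactly (0, 1)")
        for g, v in self.variances.items():
            if not v > 0:
                raise ValidationError(f"latent variance for group {g!r} must be positive")

    def moments(self, group: str) -> tuple[float, float]:
        try:
            return self.means[group], self.variances[group]
        except KeyError:
            raise ValidationError(f"no latent moments for group {group!r}")

    @property
    def groups(self) -> list[str]:
        return list(self.means)
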