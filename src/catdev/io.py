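"""CSV/YAML readers and writers for banks, response matrices, and labels.

Numeric cells are written with ``repr`` so that a write/read cycle is
bit-exact. Malformed input is reported with the offending row.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from .calibration import ResponseMatrix
from .errors import CatDevError
from .irt_models import MISSING, ItemBank, ItemParameters

__all__ = [
    "read_bank", "write_bank",
    "read_responses", "write_responses",
    "read_person_column", "write_person_column",
    "read_config",
]

_BANK_COLS = ["item_id", "source_scale", "model", "n_categories", "a",
              "b1", "b2", "b3", "b4", "criterion"]


def write_bank(bank: ItemBank, path) -> None:
    """Write a GRM/GPCM/PCM bank to CSV (empty cells for unused thresholds)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_BANK_COLS)
        for it in bank:
            if it.model == "NRM":
                raise CatDevError("NRM items have no threshold-CSV representation")
            b = list(it.thresholds) + [None] * (4 - len(it.thresholds))
            w.writerow([it.item_id, it.source_scale, it.model, it.n_categories,
                        repr(it.slope),
                        *("" if x is None else repr(float(x)) for x in b),
                        it.criterion])


def read_bank(path) -> ItemBank:
    """Read an item-bank CSV; parameter constraints are validated per item."""
    items = []
    with open(path, newline="") as fh:
        rdr = csv.DictReader(fh)
        if rdr.fieldnames is None:
            raise CatDevError(f"{path}: empty bank file")
        missing_cols = set(_BANK_COLS) - set(rdr.fieldnames)
        if missing_cols:
            raise CatDevError(f"{path}: missing columns {sorted(missing_cols)}")
        for ln, row in enumerate(rdr, start=2):
            try:
                K = int(row["n_categories"])
                bs = [float(row[f"b{i}"]) for i in range(1, K)
                      if row[f"b{i}"] != ""]
                items.append(ItemParameters(
                    item_id=row["item_id"], n_categories=K,
                    slope=float(row["a"]), thresholds=tuple(bs),
                    model=row["model"] or "GRM",
                    source_scale=row["source_scale"] or "synthetic",
                    criterion=row["criterion"] or "unknown"))
            except (CatDevError, ValueError) as exc:
                raise CatDevError(f"{path}: line {ln}: {exc}") from exc
    if not items:
        raise CatDevError(f"{path}: bank file has no items")
    return ItemBank(items)


def write_responses(responses: ResponseMatrix, path,
                    group_path=None) -> None:
    """Write a response matrix (missing responses as empty cells); the group
    column, if present, goes to ``group_path``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", *responses.item_ids])
        for pid, row in zip(responses.person_ids, responses.codes):
            w.writerow([pid, *("" if c == MISSING else int(c) for c in row)])
    if group_path is not None and responses.groups is not None:
        write_person_column(responses.person_ids, responses.groups,
                            group_path, "group")


def read_responses(path, group_path=None) -> ResponseMatrix:
    """Read a response-matrix CSV (and optionally a person-group CSV)."""
    with open(path, newline="") as fh:
        rdr = csv.reader(fh)
        try:
            header = next(rdr)
        except StopIteration:
            raise CatDevError(f"{path}: empty responses file") from None
        if not header or header[0] != "person_id":
            raise CatDevError(f"{path}: first column must be person_id")
        item_ids = header[1:]
        persons, rows = [], []
        for ln, row in enumerate(rdr, start=2):
            if len(row) != len(header):
                raise CatDevError(f"{path}: line {ln}: expected {len(header)} cells")
            persons.append(row[0])
            try:
                rows.append([MISSING if c == "" else int(c) for c in row[1:]])
            except ValueError as exc:
                raise CatDevError(f"{path}: line {ln}: {exc}") from exc
    if not persons:
        raise CatDevError(f"{path}: responses file has no persons")
    codes = np.array(rows, dtype=int)
    if np.any(codes < MISSING):
        raise CatDevError(f"{path}: negative category codes present")
    groups = None
    if group_path is not None:
        gp_persons, gvals = read_person_column(group_path, "group")
        gmap = dict(zip(gp_persons, gvals))
        try:
            groups = np.array([gmap[p] for p in persons])
        except KeyError as exc:
            raise CatDevError(f"{group_path}: missing group for person {exc}") from exc
    return ResponseMatrix(persons, item_ids, codes, groups=groups)


def write_person_column(person_ids, values, path, name: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", name])
        for pid, v in zip(person_ids, values):
            w.writerow([pid, repr(float(v)) if isinstance(v, float) else v])


def read_person_column(path, name: str):
    """Read a (person_id, value) CSV; returns (person_ids, values array)."""
    with open(path, newline="") as fh:
        rdr = csv.DictReader(fh)
        if rdr.fieldnames is None or name not in rdr.fieldnames:
            raise CatDevError(f"{path}: expected columns person_id,{name}")
        persons, vals = [], []
        for row in rdr:
            persons.append(row["person_id"])
            vals.append(row[name])
    arr = np.array(vals)
    try:
        arr = arr.astype(int)
    except ValueError:
        try:
            arr = arr.astype(float)
        except ValueError:
            pass
    return persons, arr


def read_config(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise CatDevError(f"{path}: configuration must be a mapping")
    return cfg
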