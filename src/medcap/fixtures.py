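"""Machine-readable copies of the published reference tables.

The package ships, as CSV resources, the confusion matrices of the best
published model (one per caption slot), their printed 12-column metric
tables, the per-backbone experiment grids (8 families x 24 runs), and the
family accuracy summary. They serve as oracles for the evaluation code and
as inputs to the summary operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import SlotConfusion

__all__ = ["FixtureTable", "load_fixture", "load_csv", "load_confusion",
           "load_grid", "load_metric_table", "FIXTURE_NAMES"]

_CONFUSIONS = {
    "exam_confusion": "table13",
    "body_confusion": "table15",
    "problem_confusion": "table17",
}
_GRID_TABLES = {f"table{i}": f"acc_table{i}" for i in range(4, 12)}
_FAMILY_OF_TABLE = {
    "table4": "DenseNet201", "table5": "ResNet152V2", "table6": "NASNetLarge",
    "table7": "VGG19", "table8": "Xception", "table9": "InceptionV3",
    "table10": "InceptionResNetV2", "table11": "MobileNetV2",
}

FIXTURE_NAMES = tuple(sorted(
    set(_CONFUSIONS) | {"densenet_acc", "global_acc", "family_summary"}
))


@dataclass(frozen=True)
class FixtureTable:
    name: str
    payload: object  # SlotConfusion, ndarray or DataFrame


def _resource_text(filename: str) -> str:
    ref = resources.files("medcap.data").joinpath(filename)
    try:
        return ref.read_text()
    except FileNotFoundError as exc:
        raise ValidationError(f"unknown fixture file {filename!r}") from exc


def load_csv(basename: str, as_text: bool = False) -> pd.DataFrame:
    """Raw fixture CSV (e.g. ``table13``, ``acc_table4``, ``table3``).

    ``as_text=True`` preserves the printed cell formatting (``0.00`` vs
    ``0.0``, dashes) by suppressing numeric parsing.
    """
    from io import StringIO

    return pd.read_csv(StringIO(_resource_text(basename + ".csv")),
                       dtype=str if as_text else None)


def load_confusion(basename: str) -> SlotConfusion:
    df = load_csv(basename)
    labels = tuple(df["Class"])
    counts = df.drop(columns="Class").to_numpy(dtype=np.int64)
    return SlotConfusion(labels, counts)


def load_grid(table_number: int) -> pd.DataFrame:
    """One published experiment family (24 runs) with its grid columns."""
    if table_number not in range(4, 12):
        raise ValidationError(f"no grid table {table_number}")
    return load_csv(f"acc_table{table_number}")


def load_metric_table(table_number: int) -> pd.DataFrame:
    """A printed metric table (14, 16 or 18), dashes kept as strings."""
    if table_number not in (14, 16, 18):
        raise ValidationError(f"no metric table {table_number}")
    return load_csv(f"table{table_number}", as_text=True)


def load_fixture(name: str) -> FixtureTable:
    """Look up a fixture by its logical name.

    ``exam_confusion`` / ``body_confusion`` / ``problem_confusion`` are the
    published slot confusion matrices; ``densenet_acc`` the 24 accuracies of
    the DenseNet201 family; ``global_acc`` all 192 grid accuracies;
    ``family_summary`` the published mean/std summary table.
    """
    if name in _CONFUSIONS:
        return FixtureTable(name, load_confusion(_CONFUSIONS[name]))
    if name == "densenet_acc":
        return FixtureTable(name, load_grid(4)["ACC"].to_numpy(dtype=float))
    if name == "global_acc":
        accs = np.concatenate([load_grid(i)["ACC"].to_numpy(dtype=float)
                               for i in range(4, 12)])
        return FixtureTable(name, accs)
    if name == "family_summary":
        return FixtureTable(name, load_csv("table3"))
    raise ValidationError(f"unknown fixture {name!r}")


def load_full_grid() -> pd.DataFrame:
    """All 192 published experiment records, in ID order."""
    return pd.concat([load_grid(i) for i in range(4, 12)], ignore_index=True)
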