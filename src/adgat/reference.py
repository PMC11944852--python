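"""Packaged reference resources.

* the ADG-AT reference summary table: servings per 100 g of the five ADG
  food groups and discretionary foods for each of the 101 DQES output
  items, transcribed from the published tool;
* the default DQES item-definition file (names, search terms, expected
  form, specificity) used to drive the matcher.

The reference table's SHA-256 checksum is pinned so transcription drift
fails loudly rather than silently corrupting downstream scores.
"""

from __future__ import annotations

import hashlib
from importlib import resources

from .errors import IntegrityError
from .food_model import ADGATTable, FFQItemDef, read_adgat_table, read_ffq_items

REFERENCE_TABLE_FILE = "adgat_reference_table.csv"
REFERENCE_TABLE_SHA256 = (
    "9907cdb1770867743db3144a4712811954fada38694b22c4e617bd39a7570aa5"
)
ITEMS_FILE = "dqes_items.yaml"

#: Number of DQES output items covered by the tool.
N_ITEMS = 101


def _data_path(name: str):
    return resources.files("adgat.data").joinpath(name)


def load_reference_table(*, verify_checksum: bool = True) -> ADGATTable:
    """Load the packaged 101-row ADG-AT reference table.

    Raises :class:`IntegrityError` if the packaged file's checksum does
    not match the pinned value.
    """
    path = _data_path(REFERENCE_TABLE_FILE)
    data = path.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(data).hexdigest()
        if digest != REFERENCE_TABLE_SHA256:
            raise IntegrityError(
                f"reference table checksum mismatch: expected "
                f"{REFERENCE_TABLE_SHA256}, got {digest}"
            )
    with resources.as_file(path) as p:
        table = read_adgat_table(p)
    if len(table) != N_ITEMS:
        raise IntegrityError(
            f"reference table has {len(table)} rows, expected {N_ITEMS}"
        )
    return table


def load_default_items() -> list[FFQItemDef]:
    """Load the packaged DQES item definitions (one per reference row)."""
    with resources.as_file(_data_path(ITEMS_FILE)) as p:
        items = read_ffq_items(p)
    if len(items) != N_ITEMS:
        raise IntegrityError(
            f"item definition file has {len(items)} entries, expected {N_ITEMS}"
        )
    return items
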