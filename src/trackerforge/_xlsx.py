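"""Deterministic XLSX writing helpers.

XLSX files are zip archives; both the workbook core properties and the zip
member timestamps normally embed the wall clock, which would defeat
byte-level reproducibility. These helpers pin every timestamp so that
identical content yields identical bytes.
"""

from __future__ import annotations

import re
import zipfile
from datetime import datetime
from pathlib import Path

from openpyxl import Workbook

_FIXED_STAMP = datetime(2000, 1, 1)
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)
# openpyxl stamps docProps/core.xml with the wall clock at save time
_CORE_STAMP = re.compile(
    rb"(<dcterms:(?:created|modified)[^>]*>)[^<]*(</dcterms:)")


def save_workbook_deterministic(wb: Workbook, path: Path | str) -> Path:
    """Save a workbook with pinned metadata and zip timestamps."""
    path = Path(path)
    wb.properties.created = _FIXED_STAMP
    wb.properties.modified = _FIXED_STAMP
    wb.save(path)
    normalize_zip(path)
    return path


def normalize_zip(path: Path | str) -> None:
    """Rewrite a zip archive with sorted members and zeroed timestamps."""
    path = Path(path)
    with zipfile.ZipFile(path) as zin:
        members = sorted(zin.namelist())
        payload = {name: zin.read(name) for name in members}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zout:
        for name in members:
            data = payload[name]
            if name == "docProps/core.xml":
                data = _CORE_STAMP.sub(
                    rb"\g<1>2000-01-01T00:00:00Z\g<2>", data)
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zout.writestr(info, data)
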