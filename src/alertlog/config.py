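"""Clinic-level configuration.

Office hours, Saturday flags and "the following day" are local-time concepts,
so all window arithmetic runs in one configured clinic timezone.  Timestamps
on disk stay ISO-8601 with explicit UTC offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from zoneinfo import ZoneInfo

import yaml

DEFAULT_TZ = ZoneInfo("America/New_York")


@dataclass(frozen=True)
class ClinicConfig:
    timezone: str = "America/New_York"

    @property
    def tz(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClinicConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


__all__ = ["ClinicConfig", "DEFAULT_TZ"]
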