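"""Run manifests and deterministic CSV/table output.

Every results file references exactly one manifest.  The manifest id is a
hash of the inputs that determine the numbers (config hash, seed, structure
options, package version, currency factor) — re-running a command with the
same inputs reproduces every CSV byte for byte; the wall-clock timestamp
lives only in the manifest JSON and is excluded from the id.

All computation is carried out in SGD; USD columns are derived once at
report time.  Cohort totals are displayed to whole SGD and per-exam /
per-patient figures to cents, matching the publication style; stored CSV
values keep full precision.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_table"]


@dataclasses.dataclass(frozen=True)
class RunManifest:
    config_sha256: str
    seed: int | None
    options: dict
    sgd_to_usd: float
    command: str
    version: str = __version__

    @property
    def manifest_id(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write(self, out_dir: Path) -> Path:
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"manifest_{self.manifest_id}.json"
        body = dataclasses.asdict(self)
        body["manifest_id"] = self.manifest_id
        body["created"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        path.write_text(json.dumps(body, indent=2) + "\n")
        return path

    @property
    def header_line(self) -> str:
        return f"# manifest: {self.manifest_id} (pocus-cma {self.version})"


def write_table(df: pd.DataFrame, path: Path, manifest: RunManifest) -> Path:
    """CSV with a manifest reference comment as the first line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(manifest.header_line + "\n")
        df.to_csv(fh, index=False)
    return path


def round_per_patient(x: float) -> float:
    return round(x, 2)


def round_cohort(x: float) -> int:
    return int(round(x))
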