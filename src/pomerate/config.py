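"""Layered run configuration and batch directory processing.

Parameter precedence is flags > config file > documented defaults, and the
fully resolved configuration is written next to the outputs so every result
directory records exactly how it was produced. Batch runs visit files in
lexicographic order, log-and-skip per-file failures, and exit nonzero iff
anything failed, so reruns on unchanged inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import yaml

from .errors import ConfigurationError
from .raster import RatingRecord, write_ratings_csv

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}

DEFAULTS: dict[str, object] = {
    "min_conf": 0.999,
    "top_k": 18,
    "background_max": 20,
    "min_blob_area": 500,
    "gamma": 0.25,
    "y_floor": 10,
    "l_threshold": None,   # resolved per fruit kind when unset
    "fruit": "apple",
    "min_area": 2000,
    "connectivity": 8,
    "a_threshold": 128,
    "card": None,
    "spi": None,
    "seed": 0,
}


def resolve_config(
    defaults: Mapping[str, object],
    file_config: Mapping[str, object] | None = None,
    flags: Mapping[str, object] | None = None,
) -> dict[str, object]:
    """Merge defaults, config-file values, and CLI flags (flags win).

    Keys absent from ``defaults`` are unknown and raise a
    :class:`ConfigurationError` naming them; flag values of ``None`` mean
    "not given" and are skipped.
    """
    resolved = dict(defaults)
    for layer_name, layer in (("config file", file_config), ("flags", flags)):
        if not layer:
            continue
        unknown = sorted(set(layer) - set(defaults))
        if unknown:
            raise ConfigurationError(f"unknown {layer_name} keys: {unknown}")
        for k, v in layer.items():
            if layer_name == "flags" and v is None:
                continue
            resolved[k] = v
    return resolved


def load_config_file(path: str | Path | None) -> dict[str, object]:
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must be a key/value mapping")
    return data


def write_resolved_config(config: Mapping[str, object], out_dir: str | Path) -> Path:
    """Record the resolved configuration alongside the outputs."""
    out = Path(out_dir) / "run_config.yaml"
    out.write_text(yaml.safe_dump(dict(config), sort_keys=True))
    return out


@dataclasses.dataclass(frozen=True)
class BatchSummary:
    processed: int
    skipped: int
    failures: tuple[str, ...]

    @property
    def exit_status(self) -> int:
        return 1 if self.failures else 0


def list_input_images(input_dir: str | Path) -> list[Path]:
    """Image files of a directory in deterministic lexicographic order."""
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise ConfigurationError(f"input directory does not exist: {input_dir}")
    return sorted(
        p for p in input_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )


def run_batch(
    input_dir: str | Path,
    process: Callable[[Path], Iterable[RatingRecord]],
    output_dir: str | Path,
    csv_name: str,
    config: Mapping[str, object],
    fieldnames: Sequence[str] | None = None,
) -> BatchSummary:
    """Apply ``process`` to every image of ``input_dir`` and write one CSV.

    Per-file failures are logged and skipped; the summary's exit status is
    nonzero iff any file failed. An empty input directory yields a warning
    and a header-only CSV with zero exit status.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    files = list_input_images(input_dir)
    if not files:
        logger.warning("no input images found in %s", input_dir)
    records: list[RatingRecord] = []
    failures: list[str] = []
    for path in files:
        try:
            records.extend(process(path))
        except Exception as exc:  # per-file isolation is the contract
            logger.error("failed on %s: %s", path.name, exc)
            failures.append(path.name)
    write_ratings_csv(records, output_dir / csv_name, fieldnames=fieldnames)
    write_resolved_config(config, output_dir)
    return BatchSummary(
        processed=len(files) - len(failures),
        skipped=len(failures),
        failures=tuple(failures),
    )


def parse_subimage_name(path: Path) -> tuple[str, int]:
    """Split a sub-image filename ``<stem>-<index>`` into its parts; files
    without a numeric appendix rate as fruit 1 of their own stem."""
    stem = path.stem
    if "-" in stem:
        head, _, tail = stem.rpartition("-")
        if tail.isdigit() and int(tail) >= 1:
            return head, int(tail)
    return stem, 1
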