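"""YAML configuration loading and stderr stage-timing helpers."""

from __future__ import annotations

import logging
import sys
import time
from contextlib import contextmanager
from pathlib import Path

import yaml

logger = logging.getLogger("fibroscope")


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with timestamps (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)


def load_config(path: str | Path) -> dict:
    """Load a single YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a YAML mapping")
    return cfg


@contextmanager
def stage_timer(name: str):
    """Log wall-clock duration of a pipeline stage to stderr."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
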