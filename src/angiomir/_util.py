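"""Shared error types and seeded sub-stream derivation."""

from __future__ import annotations

import zlib

import numpy as np


class AngiomirError(Exception):
    """Base class for all package errors."""


class ValidationError(AngiomirError):
    """An input violated a documented invariant."""


class ParseError(AngiomirError):
    """A text input could not be parsed; carries file position context."""


class ConfigError(AngiomirError):
    """A simulation or pipeline configuration field is invalid."""


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component random stream.

    The stream depends only on (seed, component name), so adding a new
    simulated component never perturbs the draws of an existing one.
    """
    tag = zlib.crc32(component.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
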