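"""Packaged fixture systems (text dialect, under ``rafnet/data``)."""

from __future__ import annotations

from importlib import resources

from .reaction_system import ReactionSystem, parse_system

__all__ = ["fixture_text", "load_fixture", "fixture_path", "FIXTURES"]

FIXTURES = ("eq2", "no_raf")


def fixture_text(name: str) -> str:
    """Raw text of a packaged fixture ('eq2' or 'no_raf')."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return resources.files("rafnet").joinpath("data", f"{name}.rafsys").read_text()


def load_fixture(name: str) -> ReactionSystem:
    """Parse and return a packaged fixture system."""
    return parse_system(fixture_text(name), dialect="text")


def fixture_path(name: str) -> str:
    """Filesystem path of a packaged fixture (for CLI use)."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return str(resources.files("rafnet").joinpath("data", f"{name}.rafsys"))
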