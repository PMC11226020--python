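"""Species-name canonicalization.

Point-count field sheets and classifier output spell species differently
(case, diacritics, common vs scientific name).  A :class:`SpeciesCatalog`
maps any alias to one canonical ``(scientific_name, common_name)`` pair so
the two data streams join on a single key.  Identity is keyed on the
scientific name after canonicalization; common names are display-only.
"""

from __future__ import annotations

import os
import unicodedata

import pandas as pd

from .errors import FormatError, MappingError


def _norm(name: str) -> str:
    """Case-fold, strip and remove diacritics for alias matching."""
    s = unicodedata.normalize("NFKD", str(name).strip())
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return " ".join(s.casefold().split())


class SpeciesCatalog:
    """Alias table resolving species names to canonical pairs.

    Parameters
    ----------
    pairs
        Iterable of ``(scientific_name, common_name)`` canonical pairs.
    aliases
        Optional mapping of extra alias -> scientific name.  The scientific
        and common names themselves are always registered as aliases.
    """

    def __init__(self, pairs, aliases=None):
        self._canon: dict[str, tuple[str, str]] = {}
        self._alias: dict[str, str] = {}
        for sci, common in pairs:
            self._canon[sci] = (sci, common)
            self._alias[_norm(sci)] = sci
            self._alias[_norm(common)] = sci
        for alias, sci in (aliases or {}).items():
            if sci not in self._canon:
                raise MappingError(f"alias {alias!r} points to unknown species {sci!r}")
            self._alias[_norm(alias)] = sci

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "SpeciesCatalog":
        """Build a catalog from a CSV with columns ``alias, scientific, common``."""
        df = pd.read_csv(path)
        for col in ("alias", "scientific", "common"):
            if col not in df.columns:
                raise FormatError(f"missing required column(s): {col}")
        pairs = df[["scientific", "common"]].drop_duplicates().itertuples(index=False)
        cat = cls(list(pairs))
        for row in df.itertuples(index=False):
            cat._alias[_norm(row.alias)] = row.scientific
        return cat

    def canonicalize(self, name: str, strict: bool = True):
        """Resolve ``name`` to its canonical ``(scientific, common)`` pair.

        Unknown names raise :class:`~pamval.errors.MappingError` when
        ``strict`` (the default); otherwise they return ``None`` so the caller
        can flag rather than silently drop them.  Canonical inputs map to
        themselves (idempotence).
        """
        sci = self._alias.get(_norm(name))
        if sci is None:
            if strict:
                raise MappingError(f"unknown species name: {name!r}")
            return None
        return self._canon[sci]

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self._alias

    def __len__(self) -> int:
        return len(self._canon)


def canonicalize_species(name: str, catalog: SpeciesCatalog, strict: bool = True):
    """Functional wrapper over :meth:`SpeciesCatalog.canonicalize`."""
    return catalog.canonicalize(name, strict=strict)
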