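"""Loading of the editable plain-text lexicons shipped with the package.

Every rule list (triggers, POS lexicon, pattern inventory, gazetteers) is a
resource file so that curators can extend coverage without touching code.
Lines starting with ``#`` and blank lines are ignored. A different lexicon
directory can be passed to any loader.
"""

from __future__ import annotations

import functools
from importlib import resources as _ilr
from pathlib import Path
from typing import List, Optional, Tuple

def resource_lines(name: str, directory: Optional[Path] = None) -> List[str]:
    if directory is not None:
        text = (Path(directory) / name).read_text(encoding="utf-8")
    else:
        text = (
            _ilr.files("phosphomine") / "resources" / name
        ).read_text(encoding="utf-8")
    out = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        out.append(line)
    return out


def load_lexicon_pairs(
    name: str, directory: Optional[Path] = None
) -> List[Tuple[str, str]]:
    """TSV with exactly two columns: (word, value)."""
    pairs = []
    for line in resource_lines(name, directory):
        word, value = line.split("\t")[:2]
        pairs.append((word, value))
    return pairs


def load_word_set(name: str, directory: Optional[Path] = None) -> frozenset:
    return frozenset(w.lower() for w in resource_lines(name, directory))


@functools.lru_cache(maxsize=None)
def cached_word_set(name: str) -> frozenset:
    return load_word_set(name)


@functools.lru_cache(maxsize=None)
def cached_lines(name: str) -> tuple:
    return tuple(resource_lines(name))
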