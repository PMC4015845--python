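"""Exact multi-pattern substring search (Aho-Corasick automaton).

Peptide-to-protein mapping and subset detection both reduce to the same
primitive: given a set of patterns, report which patterns occur as
contiguous substrings of a text.  The automaton guarantees no false
positives and no false negatives and scans each text once, so mapping
tens of thousands of peptides against a library is linear in total text
length rather than quadratic.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator


class SubstringIndex:
    """Aho-Corasick automaton over a fixed set of patterns.

    Parameters
    ----------
    patterns : iterable of str
        Non-empty strings to search for.  Duplicates are collapsed.
    """

    def __init__(self, patterns: Iterable[str]):
        self.patterns: list[str] = list(dict.fromkeys(patterns))
        if any(not p for p in self.patterns):
            raise ValueError("patterns must be non-empty")
        # trie as list of dicts; output[i] = pattern indices ending at node i
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[int]] = [[]]
        for pi, pat in enumerate(self.patterns):
            node = 0
            for ch in pat:
                nxt = self._goto[node].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    nxt = len(self._goto) - 1
                    self._goto[node][ch] = nxt
                node = nxt
            self._out[node].append(pi)
        # failure links by BFS; outputs are merged along failure chains
        self._fail = [0] * len(self._goto)
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[child] = self._goto[f].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] += self._out[self._fail[child]]

    def iter_matches(self, text: str) -> Iterator[tuple[int, int]]:
        """Yield ``(end_position, pattern_index)`` for every occurrence."""
        node = 0
        for i, ch in enumerate(text):
            while node and ch not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(ch, 0)
            for pi in self._out[node]:
                yield i, pi

    def patterns_in(self, text: str) -> list[str]:
        """Distinct patterns occurring in `text`, in first-occurrence order."""
        seen: dict[int, None] = {}
        for _, pi in self.iter_matches(text):
            seen.setdefault(pi, None)
        return [self.patterns[pi] for pi in seen]

    def __contains__(self, pattern: str) -> bool:
        return pattern in self.patterns
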