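"""Aho–Corasick multi-pattern string matching.

A compact automaton for simultaneous dictionary matching of many surface
strings against a sentence.  Patterns are matched literally on the string
fed to :meth:`Automaton.iter_matches`; callers who want case-insensitive
behaviour lowercase both the patterns and the text.
"""

from __future__ import annotations

from collections import deque
from typing import Iterator


class Automaton:
    """Trie with failure links over an arbitrary set of string patterns."""

    def __init__(self, patterns: list[str]):
        # node 0 is the root; each node is a dict edge table
        self._edges: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        # pattern lengths ending at each node (via its output link chain)
        self._out: list[list[int]] = [[]]
        for pat in patterns:
            self._insert(pat)
        self._build_links()

    def _insert(self, pat: str) -> None:
        if not pat:
            raise ValueError("empty pattern")
        node = 0
        for ch in pat:
            nxt = self._edges[node].get(ch)
            if nxt is None:
                nxt = len(self._edges)
                self._edges.append({})
                self._fail.append(0)
                self._out.append([])
                self._edges[node][ch] = nxt
            node = nxt
        if len(pat) not in self._out[node]:
            self._out[node].append(len(pat))

    def _build_links(self) -> None:
        queue: deque[int] = deque()
        for child in self._edges[0].values():
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._edges[node].items():
                queue.append(child)
                fail = self._fail[node]
                while fail and ch not in self._edges[fail]:
                    fail = self._fail[fail]
                self._fail[child] = self._edges[fail].get(ch, 0)
                if self._fail[child] == child:
                    self._fail[child] = 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]

    def iter_matches(self, text: str) -> Iterator[tuple[int, int]]:
        """Yield (start, end) half-open spans of every pattern occurrence."""
        node = 0
        for i, ch in enumerate(text):
            while node and ch not in self._edges[node]:
                node = self._fail[node]
            node = self._edges[node].get(ch, 0)
            for length in self._out[node]:
                yield i + 1 - length, i + 1
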