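"""Global minimizer index over a PanRG: hash -> (locus, k-mer-graph node)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .kmergraph import KmerGraph
from .sketch import MinimizerParams


@dataclass
class PanRGIndex:
    params: MinimizerParams
    entries: dict[int, list[tuple[str, int]]] = field(default_factory=dict)

    def lookup(self, h: int) -> list[tuple[str, int]]:
        return self.entries.get(h, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": {"w": self.params.w, "k": self.params.k, "hash_fn_id": self.params.hash_fn_id},
                "entries": {str(h): v for h, v in self.entries.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PanRGIndex":
        d = json.loads(text)
        params = MinimizerParams(**d["params"])
        entries = {int(h): [(l, int(n)) for l, n in v] for h, v in d["entries"].items()}
        return cls(params, entries)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path, expect: MinimizerParams | None = None) -> "PanRGIndex":
        idx = cls.from_json(Path(path).read_text())
        if expect is not None and (
            expect.w != idx.params.w or expect.k != idx.params.k or expect.hash_fn_id != idx.params.hash_fn_id
        ):
            raise ValueError("index was built with different (w, k, hash) parameters")
        return idx


def build_index(kmer_graphs: list[KmerGraph]) -> PanRGIndex:
    """Map every minimizer hash to all (locus, node) occurrences."""
    if not kmer_graphs:
        raise ValueError("no k-mer graphs to index")
    params = kmer_graphs[0].params
    for kg in kmer_graphs:
        if kg.params != params:
            raise ValueError("all k-mer graphs must share (w, k, hash) parameters")
    idx = PanRGIndex(params)
    for kg in kmer_graphs:
        for node in kg.real_nodes:
            idx.entries.setdefault(node.hash, []).append((kg.locus_id, node.id))
    return idx
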