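"""Minimal GFF3 writer.

Internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive with the version pragma and RFC-3986-style attribute escaping.
Features on a circular sequence that wrap the origin are emitted as two
parts sharing one ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_ESCAPE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "%": "%25",
           "\t": "%09", "\n": "%0A"}


def _escape(value: str) -> str:
    return "".join(_ESCAPE.get(c, c) for c in str(value))


@dataclass
class GFFFeature:
    seqid: str
    type: str
    start: int            # 0-based
    end: int              # half-open
    strand: str = "."
    source: str = "mobscan"
    score: str = "."
    attributes: dict = field(default_factory=dict)

    def lines(self, seq_length: int | None = None) -> list[str]:
        attrs = ";".join(f"{_escape(k)}={_escape(v)}"
                         for k, v in self.attributes.items())
        if seq_length is not None and self.end > seq_length:
            # wrapped circular feature: two parts joined by ID
            spans = [(self.start, seq_length), (0, self.end - seq_length)]
        else:
            spans = [(self.start, self.end)]
        out = []
        for s, e in spans:
            out.append("\t".join([
                self.seqid, self.source, self.type, str(s + 1), str(e),
                self.score, self.strand, ".", attrs or ".",
            ]))
        return out


def write_gff3(path_or_handle, features: list[GFFFeature],
               seq_lengths: dict[str, int] | None = None) -> None:
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for sid, length in seq_lengths.items():
                fh.write(f"##sequence-region {sid} 1 {length}\n")
        ordered = sorted(features, key=lambda f: (f.seqid, f.start, f.end, f.type))
        for feat in ordered:
            length = seq_lengths.get(feat.seqid) if seq_lengths else None
            for line in feat.lines(length):
                fh.write(line + "\n")
    finally:
        if own:
            fh.close()
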