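"""Reference protein panels: IEPs with class labels and domain coordinates,
integron integrases (intI) and IS200/605 transposase proteins (tnpA/tnpB).

Panels are labeled protein FASTA files whose headers carry key=value tokens::

    >IEP_CL1_1 role=iep class=CL1 domains=RT0:0-35;RT1:35-75;...;X:310-380

The package also ships deterministic *synthetic* panels (random proteins
with the same labeled structure, YADD planted inside RT5) so the whole
pipeline is exercisable without any database download; they are stand-ins
for curated group II intron / integrase / transposase reference sets and
carry no biological sequence content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# fixed IEP domain layout (aa coordinates, 0-based half-open) used by the
# synthetic panel; real panels may carry their own coordinates per entry
IEP_DOMAIN_LAYOUT: dict[str, tuple[int, int]] = {
    "RT0": (0, 35), "RT1": (35, 75), "RT2": (75, 115), "RT3": (115, 155),
    "RT4": (155, 195), "RT5": (195, 240), "RT6": (240, 275), "RT7": (275, 310),
    "X": (310, 380),
}
IEP_LENGTH = 380
YADD_POSITION = 215  # inside RT5

IEP_CLASSES = ("ML", "CL1", "CL2", "A", "B", "C", "D", "E")

# IEP class -> ribozyme class of the associated intron RNA
RIBOZYME_CLASS = {
    "ML": "IIA", "CL1": "IIB", "CL2": "IIB", "A": "IIA/B",
    "B": "IIB", "C": "IIC", "D": "IIB", "E": "IIB",
}


@dataclass
class PanelEntry:
    """One labeled reference protein."""

    id: str
    role: str                      # "iep" | "intI" | "tnpA" | "tnpB"
    label: str                     # IEP class, or gene name for intI/tnp
    protein: str
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)

    def header(self) -> str:
        parts = [self.id, f"role={self.role}", f"class={self.label}"]
        if self.domains:
            dom = ";".join(f"{n}:{s}-{e}" for n, (s, e) in self.domains.items())
            parts.append(f"domains={dom}")
        return " ".join(parts)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float,
                    protected: tuple[int, int] | None = None) -> str:
    out = list(protein)
    for i in range(len(out)):
        if protected and protected[0] <= i < protected[1]:
            continue
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def synthetic_iep_panel(seed: int = 20210301, members_per_class: int = 2,
                        divergence: float = 0.08) -> list[PanelEntry]:
    """Deterministic synthetic IEP panel: one ancestor per class, members
    derived by point substitutions; YADD planted inside RT5 for every entry.
    """
    rng = np.random.default_rng(seed)
    entries: list[PanelEntry] = []
    for cls in IEP_CLASSES:
        ancestor = list(_random_protein(rng, IEP_LENGTH))
        ancestor[YADD_POSITION:YADD_POSITION + 4] = "YADD"
        ancestor = "".join(ancestor)
        for m in range(members_per_class):
            prot = ancestor if m == 0 else _mutate_protein(
                rng, ancestor, divergence,
                protected=(YADD_POSITION, YADD_POSITION + 4))
            entries.append(PanelEntry(
                id=f"IEP_{cls}_{m + 1}", role="iep", label=cls,
                protein=prot, domains=dict(IEP_DOMAIN_LAYOUT)))
    return entries


def synthetic_inti_panel(seed: int = 915, n: int = 3) -> list[PanelEntry]:
    rng = np.random.default_rng(seed)
    ancestor = _random_protein(rng, 320)
    return [PanelEntry(id=f"intI_{i + 1}", role="intI", label="intI",
                       protein=(ancestor if i == 0
                                else _mutate_protein(rng, ancestor, 0.12)))
            for i in range(n)]


def synthetic_tnp_panel(seed: int = 605) -> list[PanelEntry]:
    """tnpA (HUH transposase, short) and tnpB (accessory, long) references."""
    rng = np.random.default_rng(seed)
    tnpa = _random_protein(rng, 150)
    tnpb = _random_protein(rng, 400)
    return [
        PanelEntry(id="tnpA_1", role="tnpA", label="tnpA", protein=tnpa),
        PanelEntry(id="tnpA_2", role="tnpA", label="tnpA",
                   protein=_mutate_protein(rng, tnpa, 0.10)),
        PanelEntry(id="tnpB_1", role="tnpB", label="tnpB", protein=tnpb),
        PanelEntry(id="tnpB_2", role="tnpB", label="tnpB",
                   protein=_mutate_protein(rng, tnpb, 0.10)),
    ]


@dataclass
class ReferencePanels:
    """The three labeled panels the pipeline consumes."""

    iep: list[PanelEntry]
    inti: list[PanelEntry]
    tnp: list[PanelEntry]

    @classmethod
    def default(cls) -> "ReferencePanels":
        return cls(iep=synthetic_iep_panel(), inti=synthetic_inti_panel(),
                   tnp=synthetic_tnp_panel())

    def validate(self) -> None:
        if not self.iep:
            raise ConfigurationError("IEP reference panel is empty")
        for e in self.iep:
            if not e.domains:
                raise ConfigurationError(
                    f"IEP panel entry {e.id} lacks domain annotations")


def write_panel_fasta(path, entries: list[PanelEntry], width: int = 70) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.header()}\n")
            for i in range(0, len(e.protein), width):
                fh.write(e.protein[i:i + width] + "\n")


def read_panel_fasta(path) -> list[PanelEntry]:
    entries: list[PanelEntry] = []
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if header is not None:
                    entries.append(_parse_entry(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        entries.append(_parse_entry(header, "".join(chunks)))
    if not entries:
        raise ConfigurationError(f"{path}: empty reference panel")
    return entries


def _parse_entry(header: str, protein: str) -> PanelEntry:
    tokens = header.split()
    ident = tokens[0]
    kv = dict(t.split("=", 1) for t in tokens[1:] if "=" in t)
    domains: dict[str, tuple[int, int]] = {}
    for item in filter(None, kv.get("domains", "").split(";")):
        name, span = item.split(":")
        s, e = span.split("-")
        domains[name] = (int(s), int(e))
    return PanelEntry(id=ident, role=kv.get("role", "iep"),
                      label=kv.get("class", ""), protein=protein,
                      domains=domains)
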