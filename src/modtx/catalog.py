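"""Gene co-expression module catalogs, probe annotation, and membership resolution.

Blood transcriptional module analysis assigns microarray probes to predefined
co-expression modules — gene sets such as the 27 whole-blood modules
M1.1–M3.9 (plasma cells, platelets, interferon, inflammation, ...) — via
Entrez gene identifiers.  This module provides the data model for such
catalogs, a GMT reader/writer, a two-column probe→Entrez annotation format,
and the resolution of each probe to the set of modules containing its gene.

Modules need not be disjoint: a gene present in several catalog entries puts
its probes in all of them, and per-module statistics downstream are computed
independently, so overlap is harmless.  Probes without an annotated gene, or
whose gene is in no module, are retained with an empty membership set and act
as background in contingency-table tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Module",
    "ModuleCatalog",
    "ModuleMembership",
    "BLOOD_MODULE_IDS",
    "BLOOD_MODULE_LABELS",
    "read_gmt",
    "write_gmt",
    "read_probe_annotation",
    "write_probe_annotation",
    "resolve_membership",
]

#: The 27 whole-blood module identifiers in figure/table order.  Note the
#: historical numbering: M2.10 does not exist while M2.11 does.
BLOOD_MODULE_IDS: tuple[str, ...] = (
    "M1.1", "M1.2", "M1.3", "M1.4", "M1.5", "M1.6", "M1.7", "M1.8",
    "M2.1", "M2.2", "M2.3", "M2.4", "M2.5", "M2.6", "M2.7", "M2.8",
    "M2.9", "M2.11",
    "M3.1", "M3.2", "M3.3", "M3.4", "M3.5", "M3.6", "M3.7", "M3.8", "M3.9",
)

#: Biology labels for the modules that have an accepted interpretation;
#: modules absent from this table are known only by number.
BLOOD_MODULE_LABELS: dict[str, str] = {
    "M1.1": "plasma cells",
    "M1.2": "platelets",
    "M1.3": "B cells",
    "M1.5": "myeloid",
    "M1.7": "MHC/ribosomal",
    "M2.1": "cytotoxic T cells",
    "M2.2": "neutrophils",
    "M2.3": "erythrocytes",
    "M2.4": "MHC/ribosomal",
    "M2.6": "myeloid",
    "M2.8": "T cells",
    "M3.1": "interferon",
    "M3.2": "inflammation",
    "M3.3": "inflammation",
}


@dataclass(frozen=True)
class Module:
    """One named gene set: identifier, free-text biology label, Entrez IDs."""

    module_id: str
    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.module_id!r} has an empty gene set")


@dataclass
class ModuleCatalog:
    """An ordered collection of modules with unique identifiers.

    Order is preserved exactly as given (figures iterate modules in catalog
    order), and every gene set is non-empty.
    """

    modules: list[Module] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for mod in self.modules:
            if mod.module_id in seen:
                raise ValueError(f"duplicate module id {mod.module_id!r}")
            seen.add(mod.module_id)

    @property
    def module_ids(self) -> tuple[str, ...]:
        return tuple(m.module_id for m in self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[Module]:
        return iter(self.modules)

    def __getitem__(self, module_id: str) -> Module:
        for mod in self.modules:
            if mod.module_id == module_id:
                return mod
        raise KeyError(module_id)

    def gene_to_modules(self) -> dict[str, frozenset[str]]:
        """Invert the catalog: Entrez gene ID -> ids of modules containing it."""
        out: dict[str, set[str]] = {}
        for mod in self.modules:
            for gene in mod.genes:
                out.setdefault(gene, set()).add(mod.module_id)
        return {g: frozenset(ms) for g, ms in out.items()}


@dataclass
class ModuleMembership:
    """Per-probe module assignment plus the catalog's module ordering.

    ``probes`` maps every input probe ID (membership is total over the probes
    it was resolved for) to the — possibly empty — set of modules containing
    its gene.  ``module_ids`` preserves catalog order for downstream iteration.
    """

    probes: dict[str, frozenset[str]]
    module_ids: tuple[str, ...]

    def probes_in(self, module_id: str) -> list[str]:
        return [p for p, mods in self.probes.items() if module_id in mods]

    def __len__(self) -> int:
        return len(self.probes)


def read_gmt(path: str | Path) -> ModuleCatalog:
    """Read a tab-delimited GMT gene-set file into a catalog.

    Each line is ``name<TAB>description<TAB>gene1[<TAB>gene2 ...]``; the
    description column is stored as the module label.  Duplicate set names
    and empty gene lists are errors naming the offending line.
    """
    path = Path(path)
    modules: list[Module] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(fields)} fields)"
                )
            name, label = fields[0], fields[1]
            genes = [g for g in fields[2:] if g.strip()]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate module name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: module {name!r} has no genes")
            seen.add(name)
            modules.append(Module(name, label, frozenset(genes)))
    return ModuleCatalog(modules)


def write_gmt(catalog: ModuleCatalog, path: str | Path) -> None:
    """Write a catalog back to GMT, preserving module order.

    Gene IDs within a set are written sorted for a stable round trip of the
    set contents (GMT does not define within-set order).
    """
    path = Path(path)
    with path.open("w") as fh:
        for mod in catalog:
            genes = "\t".join(sorted(mod.genes, key=_gene_sort_key))
            fh.write(f"{mod.module_id}\t{mod.label}\t{genes}\n")


def _gene_sort_key(gene: str) -> tuple[int, str]:
    # numeric Entrez IDs sort numerically, anything else lexically after
    return (0, gene.zfill(12)) if gene.isdigit() else (1, gene)


def read_probe_annotation(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``probe_id<TAB>entrez_id`` (with header) mapping.

    Unmapped probes must simply be absent from the file; empty Entrez fields
    are rejected so that "unmapped" is never encoded as an empty string.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["probe_id", "entrez_id"]:
            raise ValueError(
                f"{path}: expected header 'probe_id\\tentrez_id', got {header!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}:{lineno}: malformed annotation row {line!r}")
            probe, entrez = fields
            if probe in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate probe id {probe!r}")
            mapping[probe] = entrez
    return mapping


def write_probe_annotation(mapping: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("probe_id\tentrez_id\n")
        for probe, entrez in mapping.items():
            fh.write(f"{probe}\t{entrez}\n")


def resolve_membership(
    catalog: ModuleCatalog,
    annotation: Mapping[str, str],
    probe_ids: Sequence[str] | Iterable[str],
) -> ModuleMembership:
    """Map every probe to the set of modules whose gene set contains its gene.

    Membership is defined for every input probe: unannotated probes, and
    probes whose gene is in no module, get an empty set (they remain as
    background probes).  A gene shared by several modules puts the probe in
    all of them.
    """
    probe_ids = list(probe_ids)
    if len(set(probe_ids)) != len(probe_ids):
        raise ValueError("probe_ids must be unique")
    gene_map = catalog.gene_to_modules()
    empty: frozenset[str] = frozenset()
    probes = {
        p: gene_map.get(annotation.get(p, ""), empty) for p in probe_ids
    }
    return ModuleMembership(probes=probes, module_ids=catalog.module_ids)
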