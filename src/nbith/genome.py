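"""Genome coordinate model and event-calling configuration.

The genome model packages everything the event caller needs to anchor
aberrations to chromosome arms: per-chromosome lengths, centromere
intervals (the gap between the p and q arm), a small gene catalogue
(TERT, ATRX, plus MYCN/ALK for amplification tagging), and the two
catalogues of recurrent segmental chromosomal aberrations (SCAs) in
neuroblastoma — the "typical" set (1p-, +1q, +2p, 3p-, 4p-, 11q-, +17q)
and the frequently observed "atypical" set (+6p, 6q-, +7q, 9p-, +12q,
14q-, 19p-, 21q-).

All coordinates are 0-based, half-open.  SEG-style input (1-based,
inclusive) is converted on read by :mod:`nbith.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

__all__ = [
    "Arm",
    "Chromosome",
    "GenomeModel",
    "EventCallingConfig",
    "load_genome",
    "write_genome",
    "parse_signed_arm",
    "format_signed_arm",
    "TYPICAL_SCAS",
    "ATYPICAL_SCAS",
]

#: Recurrent segmental aberrations treated as "typical" of high-risk NB.
TYPICAL_SCAS = frozenset({"1p-", "+1q", "+2p", "3p-", "4p-", "11q-", "+17q"})

#: Frequently observed aberrations outside the typical set.
ATYPICAL_SCAS = frozenset(
    {"+6p", "6q-", "+7q", "9p-", "+12q", "14q-", "19p-", "21q-"}
)

_SIGNED_ARM_RE = re.compile(r"^(\+?)([0-9XY]{1,2})([pq])([-−–]?)$")


def parse_signed_arm(label: str) -> tuple[str, str]:
    """Parse a signed arm label like ``+17q`` or ``11q-`` into (arm, direction).

    Accepts ASCII hyphen as well as unicode minus/en-dash for losses.
    Returns e.g. ``("17q", "gain")`` / ``("11q", "loss")``.
    """
    m = _SIGNED_ARM_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed signed arm label: {label!r}")
    plus, chrom, arm, minus = m.groups()
    if bool(plus) == bool(minus):
        raise ValueError(f"ambiguous sign in arm label: {label!r}")
    return chrom + arm, "gain" if plus else "loss"


def format_signed_arm(arm: str, direction: str) -> str:
    if direction == "gain":
        return "+" + arm
    if direction == "loss":
        return arm + "-"
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class Arm:
    chrom: str
    label: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.label}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: tuple[int, int]


@dataclass(frozen=True)
class GenomeModel:
    build_name: str
    chromosomes: dict[str, Chromosome]
    arms: dict[str, Arm]  # keyed by arm name, e.g. "17q"
    gene_catalog: dict[str, tuple[str, int, int]]  # symbol -> (chrom, start, end)
    typical_sca_catalog: frozenset[str] = TYPICAL_SCAS
    atypical_sca_catalog: frozenset[str] = ATYPICAL_SCAS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for chrom in self.chromosomes.values():
            arms = self.chrom_arms(chrom.name)
            if not arms:
                raise ValueError(f"chromosome {chrom.name} has no arms")
            for a in arms:
                if not (0 <= a.start < a.end <= chrom.length):
                    raise ValueError(
                        f"arm {a.name} [{a.start}, {a.end}) outside "
                        f"chromosome bounds [0, {chrom.length})"
                    )
            if len(arms) == 2:
                p, q = sorted(arms, key=lambda a: a.label)
                if p.label != "p" or q.label != "q":
                    raise ValueError(f"duplicate arm labels on {chrom.name}")
                if p.end > q.start:
                    raise ValueError(
                        f"overlapping p/q arms on chromosome {chrom.name}"
                    )
        for sym, (chrom, start, end) in self.gene_catalog.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"gene {sym} on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chromosomes[chrom].length):
                raise ValueError(f"gene {sym} outside chromosome bounds")
        overlap = self.typical_sca_catalog & self.atypical_sca_catalog
        if overlap:
            raise ValueError(f"catalogues overlap: {sorted(overlap)}")
        for label in self.typical_sca_catalog | self.atypical_sca_catalog:
            arm, _ = parse_signed_arm(label)
            if arm not in self.arms:
                raise ValueError(f"catalogue arm {arm} not in arm table")

    def chrom_arms(self, chrom: str) -> list[Arm]:
        return sorted(
            (a for a in self.arms.values() if a.chrom == chrom),
            key=lambda a: a.label,
        )

    def arm_at(self, chrom: str, pos: int) -> str | None:
        """Arm name containing position ``pos``, or None (centromere/out)."""
        for a in self.chrom_arms(chrom):
            if a.start <= pos < a.end:
                return a.name
        return None

    def catalog_label(self, arm: str, direction: str) -> str:
        signed = format_signed_arm(arm, direction)
        if signed in self.typical_sca_catalog:
            return "typical"
        if signed in self.atypical_sca_catalog:
            return "atypical"
        return "other"

    def with_catalogs(
        self, typical: set[str] | None = None, atypical: set[str] | None = None
    ) -> "GenomeModel":
        """Return a copy with user-overridden SCA catalogues."""
        return replace(
            self,
            typical_sca_catalog=frozenset(
                typical if typical is not None else self.typical_sca_catalog
            ),
            atypical_sca_catalog=frozenset(
                atypical if atypical is not None else self.atypical_sca_catalog
            ),
        )


@dataclass(frozen=True)
class EventCallingConfig:
    """Thresholds of the genomic-event caller and the ITH classifier.

    Sizes are in base pairs.  An aberration shorter than ``focal_max_size``
    is focal (FSCA); at or above ``min_sca_size`` it is segmental (SCA) —
    the defaults make this a single 3 Mb partition.  A single aberrant run
    covering at least ``whole_chrom_fraction`` of its chromosome is a
    numerical (whole-chromosome) change and emits no SCA.
    """

    focal_max_size: int = 3_000_000
    min_sca_size: int = 3_000_000
    whole_chrom_fraction: float = 0.95
    baseline_ploidy: int = 2
    amplification_cn: int = 8
    cnloh_min_size: int = 10_000_000
    ctlp_min_switches: int = 10
    shift_tolerance: int = 5_000_000
    reciprocal_overlap: float = 0.5
    high_ith_threshold: float = 50.0
    detection_limit: float = 0.30

    def __post_init__(self) -> None:
        for name in (
            "focal_max_size",
            "min_sca_size",
            "cnloh_min_size",
            "shift_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("whole_chrom_fraction", "reciprocal_overlap", "detection_limit"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 < self.high_ith_threshold <= 100):
            raise ValueError("high_ith_threshold must be in (0, 100]")
        if self.baseline_ploidy < 1 or self.amplification_cn <= self.baseline_ploidy:
            raise ValueError("amplification_cn must exceed baseline_ploidy >= 1")
        if self.ctlp_min_switches < 2:
            raise ValueError("ctlp_min_switches must be >= 2")


_PACKAGED = {"default": "grch38", "grch38": "grch38", "grch37": "grch37"}


def _read_arm_table(lines, build_name: str) -> tuple[dict, dict]:
    chrom_rows: dict[str, list[tuple[str, int, int]]] = {}
    header = True
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header and fields[0].lower() in ("chrom", "chromosome"):
            header = False
            continue
        header = False
        if len(fields) < 4:
            raise ValueError(f"arm table line {i}: expected 4 columns")
        chrom = fields[0].removeprefix("chr")
        arm = fields[1]
        if arm not in ("p", "q"):
            raise ValueError(f"arm table line {i}: arm must be p or q")
        start, end = int(fields[2]), int(fields[3])
        chrom_rows.setdefault(chrom, []).append((arm, start, end))

    chromosomes: dict[str, Chromosome] = {}
    arms: dict[str, Arm] = {}
    for chrom, rows in chrom_rows.items():
        labels = [r[0] for r in rows]
        if sorted(labels) != sorted(set(labels)):
            raise ValueError(f"duplicate arm rows for chromosome {chrom}")
        rows = sorted(rows, key=lambda r: r[0])  # p before q
        length = max(r[2] for r in rows)
        if len(rows) == 2:
            (_, ps, pe), (_, qs, qe) = rows
            if pe > qs:
                raise ValueError(f"overlapping p/q arms on chromosome {chrom}")
            cen = (pe, qs)
        else:
            arm, s, e = rows[0]
            cen = (s, s) if arm == "q" else (e, e)
        chromosomes[chrom] = Chromosome(chrom, length, cen)
        for arm, s, e in rows:
            arms[f"{chrom}{arm}"] = Arm(chrom, arm, s, e)
    return chromosomes, arms


def _read_gene_bed(lines) -> dict[str, tuple[str, int, int]]:
    catalog = {}
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, symbol = line.split("\t")[:4]
        catalog[symbol] = (chrom.removeprefix("chr"), int(start), int(end))
    return catalog


def load_genome(
    resource_name: str = "default",
    gene_catalog_path: str | Path | None = None,
    typical: set[str] | None = None,
    atypical: set[str] | None = None,
) -> GenomeModel:
    """Load a packaged genome build or a user-supplied arm-table file.

    ``resource_name`` is ``"default"``/``"grch38"``, ``"grch37"``, or a path
    to a tab-separated arm table (chrom, arm, start, end).  The packaged
    builds ship a gene catalogue containing TERT, ATRX, MYCN and ALK; a
    user arm table may be paired with a BED gene catalogue via
    ``gene_catalog_path``.
    """
    if resource_name in _PACKAGED:
        build = _PACKAGED[resource_name]
        data = resources.files("nbith") / "data"
        arm_lines = (data / f"arms_{build}.tsv").read_text().splitlines()
        gene_lines = (data / f"genes_{build}.bed").read_text().splitlines()
        chromosomes, arms = _read_arm_table(arm_lines, build)
        genes = _read_gene_bed(gene_lines)
    else:
        path = Path(resource_name)
        if not path.exists():
            raise ValueError(
                f"unknown genome resource {resource_name!r}: not a packaged "
                f"build ({sorted(_PACKAGED)}) and no such file"
            )
        build = path.stem
        chromosomes, arms = _read_arm_table(
            path.read_text().splitlines(), build
        )
        genes = (
            _read_gene_bed(Path(gene_catalog_path).read_text().splitlines())
            if gene_catalog_path
            else {}
        )
    model = GenomeModel(build, chromosomes, arms, genes)
    if typical is not None or atypical is not None:
        model = model.with_catalogs(typical, atypical)
    return model


def write_genome(model: GenomeModel, arm_path: str | Path, gene_path: str | Path | None = None) -> None:
    """Serialize the arm table (and optionally the gene catalogue) as TSV/BED."""
    with open(arm_path, "w") as fh:
        fh.write("chrom\tarm\tstart\tend\n")
        for chrom in model.chromosomes.values():
            for a in model.chrom_arms(chrom.name):
                fh.write(f"{a.chrom}\t{a.label}\t{a.start}\t{a.end}\n")
    if gene_path is not None:
        with open(gene_path, "w") as fh:
            for sym, (chrom, s, e) in sorted(
                model.gene_catalog.items(), key=lambda kv: (kv[1][0], kv[1][1])
            ):
                fh.write(f"{chrom}\t{s}\t{e}\t{sym}\n")
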