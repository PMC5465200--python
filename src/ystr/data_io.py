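"""Reading, validation and writing of sample tables and analysis results.

The sample table is a TSV/CSV file with one row per individual carrying a
sample identifier, a population code, an optional clan label, calls for up
to 35 binary Y-SNP markers and repeat counts for 17 Y-STR loci (plus the
optional DYS19-2 duplication column).

Fifteen loci enter downstream haplotype analyses: DYS385a/b are dropped and
DYS389II is replaced by DYS389b = DYS389II - DYS389I.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

#: Binary markers of the SNP genotyping panel.
SNP_MARKERS: tuple[str, ...] = (
    "M217", "M48", "M174", "M35.1", "M78", "M123", "M285", "P15", "P303",
    "M406", "M69", "M170", "M267", "P58", "M172", "M47", "M67", "M12",
    "M92", "M20", "LLY22g", "M128", "M178", "M119", "P31", "M122", "P201",
    "M134", "M242", "M198", "M458", "M343", "M269", "M124", "M70",
)

#: Raw STR loci as genotyped (Yfiler panel order), plus the DYS19-2 duplicate.
RAW_STR_LOCI: tuple[str, ...] = (
    "DYS389I", "DYS389II", "DYS390", "DYS456", "DYS19", "DYS19-2",
    "DYS385a", "DYS385b", "DYS458", "DYS437", "DYS438", "DYS448",
    "GATA_H4", "DYS391", "DYS392", "DYS393", "DYS439", "DYS635",
)

#: The 15 loci of the analysis haplotype, in canonical order.
STR_LOCI_15: tuple[str, ...] = (
    "DYS389I", "DYS389b", "DYS390", "DYS456", "DYS19", "DYS458", "DYS437",
    "DYS438", "DYS448", "GATA_H4", "DYS391", "DYS392", "DYS393", "DYS439",
    "DYS635",
)

#: Index of DYS19 within :data:`STR_LOCI_15` (dropped under duplication).
DYS19_INDEX: int = STR_LOCI_15.index("DYS19")

#: Raw loci that must be present to derive a 15-locus haplotype.
REQUIRED_RAW_LOCI: tuple[str, ...] = tuple(
    loc for loc in RAW_STR_LOCI
    if loc not in ("DYS19-2", "DYS385a", "DYS385b")
)

ALLELE_MIN, ALLELE_MAX = 5, 60

_DERIVED_TOKENS = {"derived", "+", "d", "1"}
_ANCESTRAL_TOKENS = {"ancestral", "-", "a", "0"}
_MISSING_TOKENS = {"", "na", "nan", "?", ".", "none"}


class TableValidationError(ValueError):
    """Raised when a sample table fails validation; carries per-row messages."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "sample table validation failed:\n  " + "\n  ".join(self.problems)
        )


class HaplotypeError(ValueError):
    """Raised when a 15-locus haplotype cannot be derived from a record."""


@dataclass
class SampleRecord:
    """One genotyped individual.

    ``snp_calls`` maps marker name to ``"derived"`` or ``"ancestral"``;
    untyped markers are absent from the map. ``str_raw`` maps raw locus name
    to an integer repeat count; missing loci are absent.
    """

    sample_id: str
    population_code: str
    clan: Optional[str] = None
    snp_calls: dict[str, str] = field(default_factory=dict)
    str_raw: dict[str, int] = field(default_factory=dict)
    haplogroup: Optional[str] = None  # filled by haplogroups.assign_haplogroup

    def validate(self) -> list[str]:
        problems = []
        if not self.population_code:
            problems.append(f"{self.sample_id}: empty population code")
        for locus, value in self.str_raw.items():
            if not (ALLELE_MIN <= value <= ALLELE_MAX):
                problems.append(
                    f"{self.sample_id}: allele {value} at {locus} outside "
                    f"[{ALLELE_MIN}, {ALLELE_MAX}]"
                )
        i, ii = self.str_raw.get("DYS389I"), self.str_raw.get("DYS389II")
        if i is not None and ii is not None and ii < i:
            problems.append(
                f"{self.sample_id}: DYS389II ({ii}) < DYS389I ({i})"
            )
        return problems


@dataclass
class PopulationMeta:
    """Population-level metadata: grouping labels and coordinates."""

    population_code: str
    group_labels: dict[str, str] = field(default_factory=dict)
    latitude: Optional[float] = None
    longitude: Optional[float] = None

    def validate(self) -> list[str]:
        problems = []
        if not self.population_code:
            problems.append("empty population code")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            problems.append(
                f"{self.population_code}: latitude {self.latitude} invalid"
            )
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            problems.append(
                f"{self.population_code}: longitude {self.longitude} invalid"
            )
        return problems


@dataclass(frozen=True)
class StrHaplotype:
    """A 15-locus analysis haplotype with its haplogroup label.

    ``alleles`` follows :data:`STR_LOCI_15`; DYS389b is the derived
    difference DYS389II - DYS389I.  ``dys19_duplicated`` flags carriers of a
    second DYS19 copy: such haplotypes have DYS19 excluded from pairwise
    comparisons.
    """

    alleles: tuple[int, ...]
    haplogroup: str = ""
    dys19_duplicated: bool = False

    def __post_init__(self) -> None:
        if len(self.alleles) != len(STR_LOCI_15):
            raise HaplotypeError(
                f"expected {len(STR_LOCI_15)} alleles, got {len(self.alleles)}"
            )


def _parse_snp(token: str) -> Optional[str]:
    t = token.strip().lower()
    if t in _DERIVED_TOKENS:
        return "derived"
    if t in _ANCESTRAL_TOKENS:
        return "ancestral"
    if t in _MISSING_TOKENS:
        return None
    raise ValueError(f"unrecognized SNP call {token!r}")


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_sample_table(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
) -> list[SampleRecord]:
    """Read a TSV/CSV sample table into :class:`SampleRecord` objects.

    ``schema`` maps canonical column names (``sample_id``, ``population``,
    ``clan``, marker and locus names) to the file's actual column headers,
    absorbing export dialects. Missing cells become missing values, never
    zeros; row order is preserved.

    Raises
    ------
    TableValidationError
        On malformed (non-integer) alleles, out-of-range values, duplicate
        sample ids, or inconsistent DYS389 pairs; all problems are listed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    colmap = dict(schema) if schema else {}

    def col(name: str) -> Optional[str]:
        actual = colmap.get(name, name)
        return actual if actual in df.columns else None

    id_col, pop_col = col("sample_id"), col("population")
    if id_col is None or pop_col is None:
        raise TableValidationError(
            ["table must contain 'sample_id' and 'population' columns "
             "(or schema-mapped equivalents)"]
        )
    clan_col = col("clan")

    records: list[SampleRecord] = []
    problems: list[str] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row[id_col]).strip()
        if sid in seen:
            raise TableValidationError([f"duplicate sample_id {sid!r}"])
        seen.add(sid)
        rec = SampleRecord(
            sample_id=sid,
            population_code=str(row[pop_col]).strip(),
            clan=(str(row[clan_col]).strip() or None) if clan_col else None,
        )
        for marker in SNP_MARKERS:
            c = col(marker)
            if c is None:
                continue
            try:
                call = _parse_snp(str(row[c]))
            except ValueError:
                problems.append(f"{sid}: bad SNP call in column {marker}")
                continue
            if call is not None:
                rec.snp_calls[marker] = call
        for locus in RAW_STR_LOCI:
            c = col(locus)
            if c is None:
                continue
            cell = str(row[c]).strip()
            if cell.lower() in _MISSING_TOKENS or cell == "—":
                continue
            try:
                value = int(cell)
            except ValueError:
                problems.append(
                    f"{sid}: non-integer allele {cell!r} in column {locus}"
                )
                continue
            rec.str_raw[locus] = value
        problems.extend(rec.validate())
        records.append(rec)
    if problems:
        raise TableValidationError(problems)
    return records


def read_population_meta(
    path: str | Path,
    scheme_columns: Optional[Sequence[str]] = None,
) -> list[PopulationMeta]:
    """Read population metadata (grouping labels + coordinates) from TSV/CSV.

    Every column other than ``population``, ``latitude`` and ``longitude`` is
    treated as a grouping scheme unless ``scheme_columns`` restricts the set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    if "population" not in df.columns:
        raise TableValidationError(["metadata must have a 'population' column"])
    reserved = {"population", "latitude", "longitude"}
    schemes = [c for c in df.columns if c not in reserved]
    if scheme_columns is not None:
        schemes = [c for c in schemes if c in set(scheme_columns)]
    metas, problems = [], []
    for _, row in df.iterrows():
        meta = PopulationMeta(
            population_code=str(row["population"]).strip(),
            group_labels={s: str(row[s]).strip() for s in schemes
                          if str(row[s]).strip()},
            latitude=float(row["latitude"]) if "latitude" in df.columns
            and str(row["latitude"]).strip() else None,
            longitude=float(row["longitude"]) if "longitude" in df.columns
            and str(row["longitude"]).strip() else None,
        )
        problems.extend(meta.validate())
        metas.append(meta)
    if problems:
        raise TableValidationError(problems)
    return metas


def derive_haplotype(record: SampleRecord, haplogroup: str) -> StrHaplotype:
    """Build the 15-locus analysis haplotype from raw Yfiler calls.

    DYS389b is computed as DYS389II - DYS389I; DYS385a/b are dropped;
    ``dys19_duplicated`` is set when a DYS19-2 allele is present.

    Raises :class:`HaplotypeError` if a required locus is missing or the
    DYS389 pair is inconsistent.
    """
    raw = record.str_raw
    missing = [loc for loc in REQUIRED_RAW_LOCI if loc not in raw]
    if missing:
        raise HaplotypeError(
            f"{record.sample_id}: missing required loci {', '.join(missing)}"
        )
    if raw["DYS389II"] < raw["DYS389I"]:
        raise HaplotypeError(
            f"{record.sample_id}: DYS389II ({raw['DYS389II']}) < "
            f"DYS389I ({raw['DYS389I']})"
        )
    alleles = []
    for locus in STR_LOCI_15:
        if locus == "DYS389b":
            alleles.append(raw["DYS389II"] - raw["DYS389I"])
        else:
            alleles.append(raw[locus])
    return StrHaplotype(
        alleles=tuple(alleles),
        haplogroup=haplogroup,
        dys19_duplicated="DYS19-2" in raw,
    )


def records_to_haplotypes(
    records: Iterable[SampleRecord],
    skip_incomplete: bool = True,
) -> tuple[list[StrHaplotype], list[SampleRecord], int]:
    """Derive haplotypes for all records carrying a haplogroup assignment.

    Returns (haplotypes, records used, number excluded for missing loci).
    Excluded samples stay available for haplogroup-frequency analyses.
    """
    haps, used, excluded = [], [], 0
    for rec in records:
        try:
            haps.append(derive_haplotype(rec, rec.haplogroup or "unresolved"))
            used.append(rec)
        except HaplotypeError:
            if not skip_incomplete:
                raise
            excluded += 1
    return haps, used, excluded


# ---------------------------------------------------------------------------
# Writers


def _fmt(x) -> str:
    if isinstance(x, bool):
        return str(x).lower()
    if isinstance(x, float):
        if math.isinf(x):
            return "inf"
        return format(x, ".6g")
    return str(x)


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, tuple)):
        return list(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _round_floats(obj):
    if isinstance(obj, float):
        return float(format(obj, ".6g")) if math.isfinite(obj) else obj
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_results(obj, path: str | Path, format: str = "json") -> None:
    """Write a result object deterministically (sorted keys, 6 sig. digits).

    Supported pairings: frequency tables and distance matrices as ``tsv``;
    median networks as ``graphml``; any dataclass-style result as ``json``.
    """
    from ystr.haplogroups import FrequencyTable
    from ystr.mj_network import MedianNetwork
    from ystr.popgen_distance import DistanceMatrix

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        if isinstance(obj, FrequencyTable):
            lines = ["population\tn\t" + "\t".join(obj.haplogroups)]
            for i, pop in enumerate(obj.populations):
                cells = [_fmt(float(v)) for v in obj.p[i]]
                lines.append(f"{pop}\t{int(obj.n[i])}\t" + "\t".join(cells))
            path.write_text("\n".join(lines) + "\n")
            return
        if isinstance(obj, DistanceMatrix):
            lines = ["\t" + "\t".join(obj.labels)]
            for i, lab in enumerate(obj.labels):
                cells = [_fmt(float(v)) for v in obj.d[i]]
                lines.append(lab + "\t" + "\t".join(cells))
            path.write_text("\n".join(lines) + "\n")
            return
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", float_format="%.6g")
            return
        raise TypeError(f"cannot write {type(obj).__name__} as TSV")
    if format == "graphml":
        if isinstance(obj, MedianNetwork):
            nx.write_graphml(obj.to_graph(), path)
            return
        raise TypeError(f"cannot write {type(obj).__name__} as GraphML")
    if format == "json":
        payload = _round_floats(json.loads(json.dumps(obj, default=_json_default)))
        path.write_text(
            json.dumps(payload, sort_keys=True, indent=1, allow_nan=True) + "\n"
        )
        return
    raise ValueError(f"unsupported format {format!r}")


def read_frequency_table(path: str | Path):
    """Re-read a TSV written by :func:`write_results` (round-trip partner)."""
    from ystr.haplogroups import FrequencyTable
    import numpy as np

    df = pd.read_csv(path, sep="\t")
    haplogroups = [c for c in df.columns if c not in ("population", "n")]
    return FrequencyTable(
        populations=list(df["population"]),
        haplogroups=haplogroups,
        p=np.asarray(df[haplogroups], dtype=float),
        n=np.asarray(df["n"], dtype=int),
    )


def write_sample_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    """Write records back to the canonical TSV dialect (read round-trips)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    markers = [m for m in SNP_MARKERS
               if any(m in r.snp_calls for r in records)]
    loci = [l for l in RAW_STR_LOCI if any(l in r.str_raw for r in records)]
    header = ["sample_id", "population", "clan"] + markers + loci
    lines = ["\t".join(header)]
    for rec in records:
        row = [rec.sample_id, rec.population_code, rec.clan or ""]
        row += [rec.snp_calls.get(m, "") for m in markers]
        row += [str(rec.str_raw[l]) if l in rec.str_raw else "" for l in loci]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def write_population_meta(metas: Sequence[PopulationMeta], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    schemes = sorted({s for m in metas for s in m.group_labels})
    header = ["population"] + schemes + ["latitude", "longitude"]
    lines = ["\t".join(header)]
    for m in metas:
        row = [m.population_code]
        row += [m.group_labels.get(s, "") for s in schemes]
        row += ["" if m.latitude is None else _fmt(m.latitude),
                "" if m.longitude is None else _fmt(m.longitude)]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
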