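"""Readers and writers for the tabular variant format, call sets and VCF.

The tabular format is TSV with eight fixed columns::

    chrom  pos  ref  alt  gene  in_dbsnp  in_cosmic  nonsynonymous

followed, for each sample, by four columns named
``<id>:<role>:depth  <id>:<role>:alt  <id>:<role>:alt_fwd  <id>:<role>:alt_rev``.
Booleans are serialized as 0/1.  Empty observation cells mean the sample was
not observed at that site.

VCF ingestion (via cyvcf2) consumes muTect-style per-sample records: total
depth from FORMAT/DP, allele depths from FORMAT/AD.  Strand-split alt counts
come from a declared pair of per-allele FORMAT fields (e.g. ADF/ADR); when
none is declared the split is imputed as (alt_count, 0) and flagged with a
warning, which deliberately fails the both-strands plasma filter.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

from .model import (
    ConfigError,
    MultiSampleVariant,
    ParseError,
    SampleObservation,
    ValidationError,
    VariantAnnotation,
    VariantKey,
    VariantTable,
)

_FIXED_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "in_dbsnp",
    "in_cosmic",
    "nonsynonymous",
)
_OBS_FIELDS = ("depth", "alt", "alt_fwd", "alt_rev")


def _parse_header(header: list[str]) -> list[tuple[str, str]]:
    """Return [(sample_id, role), ...] from the per-sample column block."""
    if tuple(header[: len(_FIXED_COLUMNS)]) != _FIXED_COLUMNS:
        raise ParseError(
            f"line 1: expected fixed columns {_FIXED_COLUMNS}, "
            f"got {tuple(header[:len(_FIXED_COLUMNS)])}"
        )
    samples: list[tuple[str, str]] = []
    rest = header[len(_FIXED_COLUMNS) :]
    if len(rest) % len(_OBS_FIELDS):
        raise ParseError(
            "line 1: per-sample columns must come in groups of "
            f"{len(_OBS_FIELDS)} ({'/'.join(_OBS_FIELDS)})"
        )
    for i in range(0, len(rest), len(_OBS_FIELDS)):
        group = rest[i : i + len(_OBS_FIELDS)]
        parts = [c.split(":") for c in group]
        if any(len(p) != 3 for p in parts):
            raise ParseError(
                f"line 1: malformed sample column(s) {group}; "
                "expected <id>:<role>:<field>"
            )
        sid, role = parts[0][0], parts[0][1]
        if any(p[0] != sid or p[1] != role for p in parts):
            raise ParseError(f"line 1: inconsistent sample block {group}")
        if tuple(p[2] for p in parts) != _OBS_FIELDS:
            raise ParseError(
                f"line 1: sample {sid!r} columns must be {_OBS_FIELDS} in order"
            )
        samples.append((sid, role))
    return samples


def _parse_bool(text: str, line_no: int, col: str) -> bool:
    if text not in ("0", "1"):
        raise ParseError(f"line {line_no}: column {col!r} must be 0 or 1, got {text!r}")
    return text == "1"


def _parse_int(text: str, line_no: int, col: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(
            f"line {line_no}: column {col!r} must be an integer, got {text!r}"
        ) from None


def read_variant_table(path: str | Path, dialect: str = "tsv") -> VariantTable:
    """Read a cohort variant table from ``path``.

    Raises :class:`ParseError` (naming the line) on malformed rows and
    :class:`ValidationError` when an observation violates its invariants
    (e.g. ``alt_count > depth``).
    """
    if dialect != "tsv":
        raise ConfigError(f"unknown dialect {dialect!r}; only 'tsv' is supported")
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("line 1: empty file, expected a header") from None
        samples = _parse_header(header)
        n_cols = len(_FIXED_COLUMNS) + len(_OBS_FIELDS) * len(samples)
        variants: list[MultiSampleVariant] = []
        roles = dict(samples)
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != n_cols:
                raise ParseError(
                    f"line {line_no}: expected {n_cols} columns, got {len(row)}"
                )
            chrom, pos_s, ref, alt, gene = row[:5]
            ann = VariantAnnotation(
                in_dbsnp=_parse_bool(row[5], line_no, "in_dbsnp"),
                in_cosmic=_parse_bool(row[6], line_no, "in_cosmic"),
                nonsynonymous=_parse_bool(row[7], line_no, "nonsynonymous"),
                gene=gene,
            )
            obs: dict[str, SampleObservation] = {}
            for j, (sid, _role) in enumerate(samples):
                cells = row[
                    len(_FIXED_COLUMNS)
                    + j * len(_OBS_FIELDS) : len(_FIXED_COLUMNS)
                    + (j + 1) * len(_OBS_FIELDS)
                ]
                if all(c == "" for c in cells):
                    continue
                vals = [
                    _parse_int(c, line_no, f"{sid}:{f}")
                    for c, f in zip(cells, _OBS_FIELDS)
                ]
                try:
                    obs[sid] = SampleObservation(*vals)
                except ValidationError as exc:
                    raise ValidationError(f"line {line_no}, sample {sid!r}: {exc}")
            variants.append(
                MultiSampleVariant(
                    chrom=chrom,
                    pos=_parse_int(pos_s, line_no, "pos"),
                    ref=ref,
                    alt=alt,
                    annotation=ann,
                    observations=obs,
                    sample_roles=dict(roles),
                )
            )
    return VariantTable(
        variants=variants,
        sample_ids=[s for s, _ in samples],
        sample_roles=roles,
    )


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write ``table`` so that :func:`read_variant_table` recovers it exactly."""
    table.validate()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = list(_FIXED_COLUMNS)
        for sid in table.sample_ids:
            role = table.sample_roles[sid]
            header += [f"{sid}:{role}:{f}" for f in _OBS_FIELDS]
        writer.writerow(header)
        for v in table:
            row = [
                v.chrom,
                v.pos,
                v.ref,
                v.alt,
                v.annotation.gene,
                int(v.annotation.in_dbsnp),
                int(v.annotation.in_cosmic),
                int(v.annotation.nonsynonymous),
            ]
            for sid in table.sample_ids:
                o = v.observations.get(sid)
                if o is None:
                    row += ["", "", "", ""]
                else:
                    row += [o.depth, o.alt_count, o.alt_fwd, o.alt_rev]
            writer.writerow(row)


def read_vcf(
    path: str | Path,
    role_map: dict[str, str],
    strand_fields: tuple[str, str] | None = None,
) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    ``role_map`` maps VCF sample names to cohort roles.  Multiallelic records
    are decomposed into one variant per alt allele.  ``strand_fields`` names
    the pair of per-allele FORMAT fields carrying forward/reverse allele
    depths (e.g. ``("ADF", "ADR")``); when ``None``, strand counts are
    imputed as ``(alt_count, 0)`` with a warning.
    """
    from cyvcf2 import VCF  # deferred: htslib import is comparatively heavy

    vcf = VCF(str(path))
    sample_index = {name: i for i, name in enumerate(vcf.samples)}
    missing = [s for s in role_map if s not in sample_index]
    if missing:
        raise ConfigError(
            f"samples {missing} in role_map absent from VCF "
            f"(VCF has {list(vcf.samples)})"
        )
    if strand_fields is None:
        warnings.warn(
            "no strand fields declared; imputing alt strand split as "
            "(alt_count, 0) — both-strand plasma filtering will reject "
            "every call",
            stacklevel=2,
        )
    sample_ids = list(role_map)
    variants: list[MultiSampleVariant] = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ParseError(
                f"{rec.CHROM}:{rec.POS}: required per-sample field 'AD' "
                "(allele depths) is missing"
            )
        dp = rec.format("DP")
        if dp is None:
            raise ParseError(
                f"{rec.CHROM}:{rec.POS}: required per-sample field 'DP' "
                "(total depth) is missing"
            )
        adf = adr = None
        if strand_fields is not None:
            adf = rec.format(strand_fields[0])
            adr = rec.format(strand_fields[1])
            for name, arr in zip(strand_fields, (adf, adr)):
                if arr is None:
                    raise ParseError(
                        f"{rec.CHROM}:{rec.POS}: declared strand field "
                        f"{name!r} is missing"
                    )
        for alt_idx, alt in enumerate(rec.ALT):
            obs: dict[str, SampleObservation] = {}
            for sid in sample_ids:
                i = sample_index[sid]
                depth = int(dp[i][0] if dp.ndim > 1 else dp[i])
                alt_count = int(ad[i][alt_idx + 1])
                if depth < 0 or alt_count < 0:  # "./." missing genotype
                    continue
                if strand_fields is not None:
                    # per-allele fields include the ref allele at index 0
                    fwd = int(adf[i][alt_idx + 1])
                    rev = int(adr[i][alt_idx + 1])
                else:
                    fwd, rev = alt_count, 0
                obs[sid] = SampleObservation(depth, alt_count, fwd, rev)
            variants.append(
                MultiSampleVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    annotation=VariantAnnotation(),
                    observations=obs,
                    sample_roles=dict(role_map),
                )
            )
    return VariantTable(
        variants=variants, sample_ids=sample_ids, sample_roles=dict(role_map)
    )


def write_call_sets(
    calls: dict[str, set[VariantKey]], path: str | Path
) -> None:
    """Write per-sample call sets as a TSV of (sample_id, chrom, pos, ref, alt)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "chrom", "pos", "ref", "alt"])
        for sid in sorted(calls):
            for key in sorted(calls[sid]):
                writer.writerow([sid, *key])


def read_call_sets(path: str | Path) -> dict[str, set[VariantKey]]:
    """Inverse of :func:`write_call_sets`."""
    calls: dict[str, set[VariantKey]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["sample_id", "chrom", "pos", "ref", "alt"]:
            raise ParseError(f"line 1: unexpected call-set header {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ParseError(f"line {line_no}: expected 5 columns")
            sid, chrom, pos, ref, alt = row
            calls.setdefault(sid, set()).add(
                (chrom, _parse_int(pos, line_no, "pos"), ref, alt)
            )
    return calls
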