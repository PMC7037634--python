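"""Expression-matrix and sample-metadata ingestion.

Parses probe-level log2 expression tables, collapses probes to gene symbols
(multi-probe genes averaged, unmapped probes deleted), parses per-sample
annotations (donor, age, sex, brain region, hemisphere) and filters samples
to the recognized brain-region vocabulary.

Conventions: gene symbols are uppercased; age is in years with birth at 0 and
prenatal samples at negative fractional years; log2 averaging happens on the
log2 values as stored (no de-logging).
"""

from __future__ import annotations

import io
import logging
from typing import IO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 16 recognized brain-region codes (cortical areas, hippocampus,
#: amygdala, striatum, mediodorsal thalamus, cerebellar cortex).
BRAIN_REGIONS: frozenset[str] = frozenset(
    {
        "OFC", "DFC", "VFC", "MFC", "M1C", "S1C", "IPC", "A1C",
        "STC", "ITC", "V1C", "HIP", "AMY", "STR", "MD", "CBC",
    }
)

METADATA_COLUMNS = ("sample_id", "donor_id", "age_years", "sex", "region", "hemisphere")

_SEX_ALIASES = {
    "f": "female", "female": "female", "w": "female",
    "m": "male", "male": "male",
}


class ExpressionFormatError(ValueError):
    """Raised when an expression or metadata table violates its layout."""


def parse_expression(stream: IO[str] | str) -> pd.DataFrame:
    """Parse a tab-delimited expression matrix (rows × samples).

    The first column holds row identifiers (probe ids, or gene symbols for an
    already-collapsed matrix); the remaining columns are samples with a
    numeric body. Returns a DataFrame indexed by the identifier column.

    Raises :class:`ExpressionFormatError` for duplicate sample columns,
    ragged rows, or non-numeric / non-finite cells (named by row and column).
    """
    text = stream if isinstance(stream, str) else stream.read()
    header = text.split("\n", 1)[0].rstrip("\r")
    samples = header.split("\t")[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ExpressionFormatError(f"duplicate sample columns: {dupes}")
    try:
        table = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ExpressionFormatError("empty expression stream") from None
    except pd.errors.ParserError as exc:
        raise ExpressionFormatError(f"ragged expression table: {exc}") from None
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].tolist()
        raise ExpressionFormatError(f"duplicate row identifiers: {dupes}")

    def _to_float(cell):
        # float() is correctly rounded, so "%.17g"-written values round-trip
        # bitwise (pd.to_numeric's fast parser can be off by one ulp)
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    numeric = table.map(_to_float)
    bad = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ExpressionFormatError(
            f"non-numeric or non-finite value {table.iloc[r, c]!r} at "
            f"(row {table.index[r]!r}, sample {table.columns[c]!r})"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = table.index.name or "id"
    return numeric.astype(float)


def parse_probe_map(stream: IO[str] | str) -> pd.Series:
    """Parse a 2-column TSV probe-id → gene-symbol map.

    Gene symbols are uppercased and stripped. A probe listed with two
    different genes is an error (the map must be many-probes-to-one-gene).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    table = pd.read_csv(stream, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ExpressionFormatError("probe map needs two columns: probe id, gene symbol")
    present = table.iloc[:, 0].notna() & table.iloc[:, 1].notna()
    probes = table.loc[present].iloc[:, 0].astype(str).str.strip()
    genes = table.loc[present].iloc[:, 1].astype(str).str.strip().str.upper()
    mapping = pd.Series(genes.to_numpy(), index=probes, name="gene")
    mapping = mapping[(mapping.index != "") & (mapping != "")]
    conflicts = mapping.groupby(level=0).nunique()
    if (conflicts > 1).any():
        raise ExpressionFormatError(
            f"probes mapped to multiple genes: {conflicts[conflicts > 1].index.tolist()}"
        )
    return mapping[~mapping.index.duplicated()]


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per mapped gene.

    Probes with no gene assignment are deleted; where several probes map to
    one gene, the per-sample arithmetic mean of their (log2) values is taken.
    Counts of deleted and averaged probes are logged.
    """
    genes = probe_matrix.index.map(probe_map)
    mapped = genes.notna()
    n_dropped = int((~mapped).sum())
    if n_dropped == len(probe_matrix):
        raise ExpressionFormatError("no probes mapped to any gene")
    kept = probe_matrix.loc[mapped]
    kept_genes = pd.Index(genes[mapped], name="gene")
    collapsed = kept.groupby(kept_genes, sort=True).mean()
    n_averaged = len(kept) - len(collapsed)
    logger.info(
        "collapsed %d probes to %d genes (%d unmapped probes deleted, "
        "%d probes merged into multi-probe genes)",
        len(probe_matrix), len(collapsed), n_dropped, n_averaged,
    )
    return collapsed


def parse_metadata(stream: IO[str] | str) -> pd.DataFrame:
    """Parse per-sample annotations into a typed metadata table.

    Expects tab-delimited columns ``sample_id, donor_id, age_years, sex,
    region, hemisphere`` (hemisphere optional; defaults to ``unknown``).
    Ages must parse as floats ≥ −0.75 (negative = prenatal years); sex codes
    F/M/female/male normalize to ``female``/``male``, anything else to
    ``unknown``. Region codes are uppercased but not filtered here — see
    :func:`filter_regions`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    table = pd.read_csv(stream, sep="\t", dtype=str)
    required = [c for c in METADATA_COLUMNS[:5] if c not in table.columns]
    if required:
        raise ExpressionFormatError(f"metadata missing required column(s): {required}")
    if "hemisphere" not in table.columns:
        table["hemisphere"] = "unknown"

    out = pd.DataFrame(
        {
            "sample_id": table["sample_id"].astype(str).str.strip(),
            "donor_id": table["donor_id"].astype(str).str.strip(),
            "sex": table["sex"].astype(str).str.strip().str.lower().map(
                lambda s: _SEX_ALIASES.get(s, "unknown")
            ),
            "region": table["region"].astype(str).str.strip().str.upper(),
            "hemisphere": table["hemisphere"]
            .fillna("unknown")
            .astype(str)
            .str.strip()
            .str.upper()
            .map(lambda h: h if h in {"L", "R"} else "unknown"),
        }
    )
    ages = pd.to_numeric(table["age_years"], errors="coerce")
    bad_age = ages.isna() | (ages < -0.75)
    if bad_age.any():
        raise ExpressionFormatError(
            f"unparsable or out-of-range ages for samples: "
            f"{out.loc[bad_age, 'sample_id'].tolist()}"
        )
    out["age_years"] = ages.astype(float)
    if out["sample_id"].duplicated().any():
        raise ExpressionFormatError(
            f"duplicate sample ids: {out.loc[out['sample_id'].duplicated(), 'sample_id'].tolist()}"
        )
    return out[list(METADATA_COLUMNS)]


def filter_regions(
    metadata: pd.DataFrame, vocabulary: frozenset[str] | set[str] = BRAIN_REGIONS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split metadata into (kept, discarded) by region-label vocabulary.

    Samples whose region label cannot be matched to the recognized codes are
    discarded; the discarded fraction is logged (prominently if everything
    was discarded).
    """
    keep = metadata["region"].isin(vocabulary)
    kept = metadata.loc[keep].reset_index(drop=True)
    discarded = metadata.loc[~keep].reset_index(drop=True)
    if len(metadata):
        frac = len(discarded) / len(metadata)
        level = logging.WARNING if kept.empty else logging.INFO
        logger.log(
            level,
            "region filter kept %d / %d samples (discarded fraction %.3f)",
            len(kept), len(metadata), frac,
        )
    return kept, discarded


def write_expression(matrix: pd.DataFrame, stream: IO[str]) -> None:
    """Write a genes × samples matrix as TSV, full float precision."""
    matrix.to_csv(stream, sep="\t", float_format="%.17g")
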