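"""Reading, validating, writing and filtering dual-polarity feature tables.

The in-memory unit of the whole pipeline is the :class:`FeatureTable`: a
samples x features nonnegative intensity matrix together with per-feature
annotations (mass, retention time, ionization polarity, provenance) and
per-sample metadata (species, condition, block, year).  Intensity 0 is the
canonical encoding of "feature absent in this sample"; blank cells in input
files are coerced to 0 and the coercion count is logged, because the
presence/absence analyses downstream require a complete matrix.

On disk a table is a trio of plain CSV/TSV files (see :func:`read_feature_table`
for the column contracts) so that fixtures stay diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POLARITIES = ("positive", "negative", "both")
PROVENANCES = ("pos_only", "neg_only", "merged")


class ValidationError(ValueError):
    """Raised when a table or its on-disk representation violates the contract."""


@dataclass(frozen=True)
class FeatureRecord:
    """One detected LC-MS feature: a (mass, retention-time) peak.

    ``provenance`` records how the feature entered the table: native to one
    ionization mode (``pos_only``/``neg_only``) or the product of
    cross-polarity merging (``merged``).  For a merged feature ``polarity``
    records which mode's intensity vector was retained.
    """

    feature_id: str
    mass: float
    rt: float
    polarity: str
    provenance: str = "pos_only"

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValidationError("feature_id must be a non-empty string")
        if not self.mass > 0:
            raise ValidationError(f"feature {self.feature_id!r}: mass must be > 0, got {self.mass}")
        if not self.rt > 0:
            raise ValidationError(f"feature {self.feature_id!r}: rt must be > 0, got {self.rt}")
        if self.polarity not in POLARITIES:
            raise ValidationError(
                f"feature {self.feature_id!r}: polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"feature {self.feature_id!r}: provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )
        if self.provenance == "merged" and self.polarity not in ("positive", "negative"):
            raise ValidationError(
                f"feature {self.feature_id!r}: a merged feature must record the retained "
                f"polarity ('positive' or 'negative'), got {self.polarity!r}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """One biological sample (one plant / one injection).

    ``condition`` is the factorial cell the sample was grown or collected
    under (e.g. ``"open+warm"``); ``block`` identifies the experimental block
    or observational site used as the permutation stratum and random effect.
    Extra metadata columns from input files are preserved in ``extra``.
    """

    sample_id: str
    species: str
    condition: str
    block: str
    year: str = "Y1"
    extra: tuple = field(default_factory=tuple)  # ((column, value), ...) preserved on round-trip

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be a non-empty string")


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with feature and sample metadata."""

    features: list[FeatureRecord]
    samples: list[SampleRecord]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        n_s, n_f = len(self.samples), len(self.features)
        if self.intensities.shape != (n_s, n_f):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{n_s} samples x {n_f} features"
            )
        dup_f = _duplicates(f.feature_id for f in self.features)
        if dup_f:
            raise ValidationError(f"duplicate feature_ids: {sorted(dup_f)}")
        dup_s = _duplicates(s.sample_id for s in self.samples)
        if dup_s:
            raise ValidationError(f"duplicate sample_ids: {sorted(dup_s)}")
        if self.intensities.size and np.nanmin(self.intensities) < 0:
            bad = np.argwhere(self.intensities < 0)[0]
            raise ValidationError(
                f"negative intensity at sample {self.samples[bad[0]].sample_id!r}, "
                f"feature {self.features[bad[1]].feature_id!r}"
            )
        if np.isnan(self.intensities).any():
            raise ValidationError("intensity matrix contains NaN; coerce missing cells to 0 on read")

    # -- convenience accessors ------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_samples, self.n_features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> np.ndarray:
        return np.array([s.condition for s in self.samples])

    @property
    def blocks(self) -> np.ndarray:
        return np.array([s.block for s in self.samples])

    def feature_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "mass": [f.mass for f in self.features],
                "rt": [f.rt for f in self.features],
                "polarity": [f.polarity for f in self.features],
                "provenance": [f.provenance for f in self.features],
            }
        )

    def sample_meta(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "sample_id": s.sample_id,
                "species": s.species,
                "condition": s.condition,
                "block": s.block,
                "year": s.year,
            }
            row.update(dict(s.extra))
            rows.append(row)
        return pd.DataFrame(rows)

    def intensity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.sample_ids, columns=self.feature_ids)

    # -- subsetting ------------------------------------------------------

    def select_features(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            features=[self.features[i] for i in idx],
            samples=list(self.samples),
            intensities=self.intensities[:, idx],
        )

    def select_samples(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            features=list(self.features),
            samples=[self.samples[i] for i in idx],
            intensities=self.intensities[idx, :],
        )

    def reorder_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing or len(sample_ids) != self.n_samples:
            raise ValidationError(f"cannot align sample lists; missing or extra ids: {missing}")
        return self.select_samples([pos[s] for s in sample_ids])


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: Path) -> str:
    return "\t" if Path(path).suffix.lower() in (".tsv", ".tab", ".txt") else ","


# ---------------------------------------------------------------------------
# on-disk trio contract
# ---------------------------------------------------------------------------

FEATURE_META_COLUMNS = ["feature_id", "mass", "rt", "polarity", "provenance"]
SAMPLE_META_COLUMNS = ["sample_id", "species", "condition", "block", "year"]


def read_feature_table(
    intensity_path: str | Path,
    feature_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> FeatureTable:
    """Read a feature table from its three-file on-disk representation.

    File contracts (CSV or TSV by extension):

    * intensity file — first column ``sample_id``, remaining columns feature
      ids, cells nonnegative reals.  Blank/NA cells are coerced to 0 and the
      coercion count is logged.
    * feature metadata — columns ``feature_id, mass, rt, polarity, provenance``.
    * sample metadata — columns ``sample_id, species, condition, block, year``
      plus free extra columns (preserved, ignored by the pipeline).
    """
    intensity_path, feature_meta_path, sample_meta_path = (
        Path(intensity_path), Path(feature_meta_path), Path(sample_meta_path))

    inten = pd.read_csv(intensity_path, sep=_sep_for(intensity_path), index_col=0)
    fmeta = pd.read_csv(feature_meta_path, sep=_sep_for(feature_meta_path), dtype={"feature_id": str})
    smeta = pd.read_csv(sample_meta_path, sep=_sep_for(sample_meta_path), dtype=str)

    missing_f = [c for c in FEATURE_META_COLUMNS if c not in fmeta.columns]
    if missing_f:
        raise ValidationError(f"feature metadata file lacks columns: {missing_f}")
    missing_s = [c for c in SAMPLE_META_COLUMNS if c not in smeta.columns]
    if missing_s:
        raise ValidationError(f"sample metadata file lacks columns: {missing_s}")

    n_missing = int(inten.isna().to_numpy().sum())
    if n_missing:
        logger.info("coerced %d missing intensity cells to 0 in %s", n_missing, intensity_path)
        inten = inten.fillna(0.0)

    if list(inten.columns) != list(fmeta["feature_id"]):
        if len(inten.columns) != len(fmeta):
            raise ValidationError(
                f"feature axis mismatch: intensity matrix has {len(inten.columns)} feature "
                f"columns but feature metadata has {len(fmeta)} rows"
            )
        if set(inten.columns) != set(fmeta["feature_id"]):
            raise ValidationError("feature axis mismatch: intensity columns and feature_id values differ")
        fmeta = fmeta.set_index("feature_id").loc[list(inten.columns)].reset_index()
    if list(inten.index.astype(str)) != list(smeta["sample_id"]):
        if len(inten.index) != len(smeta):
            raise ValidationError(
                f"sample axis mismatch: intensity matrix has {len(inten.index)} sample "
                f"rows but sample metadata has {len(smeta)} rows"
            )
        if set(inten.index.astype(str)) != set(smeta["sample_id"]):
            raise ValidationError("sample axis mismatch: intensity rows and sample_id values differ")
        smeta = smeta.set_index("sample_id").loc[list(inten.index.astype(str))].reset_index()

    features = [
        FeatureRecord(
            feature_id=str(r.feature_id), mass=float(r.mass), rt=float(r.rt),
            polarity=str(r.polarity), provenance=str(r.provenance),
        )
        for r in fmeta.itertuples(index=False)
    ]
    extra_cols = [c for c in smeta.columns if c not in SAMPLE_META_COLUMNS]
    samples = [
        SampleRecord(
            sample_id=str(row["sample_id"]), species=str(row["species"]),
            condition=str(row["condition"]), block=str(row["block"]), year=str(row["year"]),
            extra=tuple((c, row[c]) for c in extra_cols),
        )
        for _, row in smeta.iterrows()
    ]
    return FeatureTable(features=features, samples=samples, intensities=inten.to_numpy(dtype=float))


def write_feature_table(
    table: FeatureTable,
    intensity_path: str | Path,
    feature_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> None:
    """Write the three-file representation read back by :func:`read_feature_table`.

    Floats are written with 12 significant digits so a read/write round-trip
    is lossless to at least 10 significant digits.
    """
    intensity_path, feature_meta_path, sample_meta_path = (
        Path(intensity_path), Path(feature_meta_path), Path(sample_meta_path))
    for p in (intensity_path, feature_meta_path, sample_meta_path):
        p.parent.mkdir(parents=True, exist_ok=True)

    inten = table.intensity_frame()
    inten.index.name = "sample_id"
    inten.to_csv(intensity_path, sep=_sep_for(intensity_path), float_format="%.12g")
    table.feature_meta().to_csv(
        feature_meta_path, sep=_sep_for(feature_meta_path), index=False, float_format="%.12g")
    table.sample_meta().to_csv(sample_meta_path, sep=_sep_for(sample_meta_path), index=False)


def trim_rt_window(table: FeatureTable, rt_min: float, rt_max: float) -> FeatureTable:
    """Retain only features whose retention time lies in [rt_min, rt_max].

    Bounds are inclusive on both ends so boundary peaks are never silently
    dropped.  The sample list is unchanged; an empty result is valid and
    only warned about.
    """
    if not rt_min < rt_max:
        raise ValueError(f"rt_min must be < rt_max, got [{rt_min}, {rt_max}]")
    keep = [i for i, f in enumerate(table.features) if rt_min <= f.rt <= rt_max]
    n_dropped = table.n_features - len(keep)
    if n_dropped:
        logger.info("trim_rt_window [%g, %g]: dropped %d of %d features",
                    rt_min, rt_max, n_dropped, table.n_features)
    if not keep:
        logger.warning("trim_rt_window [%g, %g]: no features retained", rt_min, rt_max)
    return table.select_features(keep)
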