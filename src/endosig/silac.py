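"""Post-processing of SILAC (phospho)proteomics ratio tables.

Consumes MaxQuant-style tab-delimited output ("proteinGroups.txt" /
"Phospho (STY)Sites.txt" dialects) and carries a forward/reverse label-swap
experiment pair through the standard post-processing chain:

  parse -> filter (decoys, contaminants, low-peptide, localization)
        -> merge duplicate entries -> log2-transform, center, orient
        -> combine replicates -> flag |log2c| > 2 SD as significant
        -> impute missing values for display only
        -> Fisher / hypergeometric gene-set over-representation.

Ratios are heavy/light (H/L).  Orientation is defined so that positive
centered log2 values always mean "higher in the mutant condition"; which
SILAC channel carries the mutant in the forward experiment is experiment
metadata and must be supplied by the caller — there is no safe default.

Missing ratios stay missing through the statistics; imputed values exist for
visualization only and never drive significance.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: column-name mapping from the MaxQuant dialect to internal names
_COLUMN_MAP = {
    "Proteins": "proteins",
    "Gene names": "gene_names",
    "Amino acid": "amino_acid",
    "Position": "position",
    "Localization prob": "localization_prob",
    "Unique peptides": "unique_peptides",
    "Ratio H/L normalized": "ratio_hl",
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
}
_MANDATORY = ["Proteins", "Gene names", "Localization prob",
              "Ratio H/L normalized", "Reverse", "Potential contaminant"]

FILTER_RULES = ("reverse", "contaminant", "low_peptide", "low_localization")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def records_from_frame(df: pd.DataFrame, origin: str = "<frame>") -> pd.DataFrame:
    """Convert a MaxQuant-dialect table (string cells) to typed site records.

    "+" flags become booleans; unparseable ratio or probability cells become
    missing, one warning each.  ``origin`` names the source in messages.
    """
    df = df.astype(str).replace({"nan": "NaN", "<NA>": ""})
    missing_cols = [c for c in _MANDATORY if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{origin}: missing mandatory column(s) {missing_cols}")

    out = pd.DataFrame(index=df.index)
    for raw, name in _COLUMN_MAP.items():
        if raw not in df.columns:
            continue
        col = df[raw]
        if name in ("reverse", "contaminant"):
            out[name] = col.str.strip() == "+"
        elif name in ("ratio_hl", "localization_prob"):
            vals = pd.to_numeric(col.replace("", np.nan), errors="coerce")
            bad = vals.isna() & ~col.str.strip().isin(["", "NaN", "nan", "NA"])
            for i in df.index[bad]:
                warnings.warn(
                    f"{origin} row {i}: unparseable {raw!r} value {col[i]!r}; "
                    "treated as missing"
                )
            out[name] = vals
        elif name in ("position", "unique_peptides"):
            out[name] = pd.to_numeric(col.replace("", np.nan),
                                      errors="coerce").astype("Int64")
        else:
            out[name] = col

    if (out["ratio_hl"] <= 0).any():
        raise ValueError(f"{origin}: non-positive H/L ratio encountered")
    if "localization_prob" in out.columns:
        lp = out["localization_prob"].dropna()
        if ((lp < 0) | (lp > 1)).any():
            raise ValueError(f"{origin}: localization probability outside [0, 1]")
    return out


def parse_table(path: str | Path,
                protein_groups_path: str | Path | None = None) -> pd.DataFrame:
    """Parse one MaxQuant-dialect phosphosite (or protein-group) table.

    Returns a typed frame with internal column names.  If the table lacks a
    "Unique peptides" column, a companion ``protein_groups_path`` is required
    and peptide counts are joined in by protein identifier.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = records_from_frame(raw, origin=str(path))
    if "unique_peptides" not in out.columns:
        if protein_groups_path is None:
            raise ValueError(
                f"{path}: no 'Unique peptides' column and no protein-groups "
                "table supplied to join peptide counts from"
            )
        pg = parse_table(protein_groups_path)
        counts = pg.set_index("proteins")["unique_peptides"]
        out["unique_peptides"] = out["proteins"].map(counts)
    return out


def parse_tables(protein_groups_path: str | Path,
                 phospho_sites_path: str | Path) -> pd.DataFrame:
    """Parse a proteinGroups/phosphosites file pair into site records."""
    return parse_table(phospho_sites_path, protein_groups_path=protein_groups_path)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------


def filter_records(records: pd.DataFrame, min_unique: int = 2,
                   min_loc_prob: float = 0.75
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop decoy, contaminant, low-evidence and poorly localized records.

    Rules, applied in order of precedence (each row counted under the first
    rule it violates): reverse-database hit, potential contaminant, fewer
    than ``min_unique`` unique peptides, localization probability below
    ``min_loc_prob``.  Returns the kept records and per-rule drop counts;
    ``len(kept) + sum(counts.values()) == len(records)`` always holds.
    """
    reasons = pd.Series("", index=records.index, dtype=object)
    reasons[records["reverse"]] = "reverse"
    mask = (reasons == "") & records["contaminant"]
    reasons[mask] = "contaminant"
    if "unique_peptides" in records.columns:
        low_pep = records["unique_peptides"].fillna(0) < min_unique
        mask = (reasons == "") & low_pep
        reasons[mask] = "low_peptide"
    if "localization_prob" in records.columns:
        low_loc = records["localization_prob"].fillna(0.0) < min_loc_prob
        mask = (reasons == "") & low_loc
        reasons[mask] = "low_localization"
    counts = {rule: int((reasons == rule).sum()) for rule in FILTER_RULES}
    kept = records[reasons == ""].copy()
    return kept, counts


def _site_key_columns(records: pd.DataFrame) -> list[str]:
    cols = ["gene_names", "proteins"]
    for c in ("amino_acid", "position"):
        if c in records.columns:
            cols.append(c)
    return cols


def merge_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate entries sharing one (gene name, protein ID) key.

    Ratios merge as the median on the log2 scale (geometric median on the
    ratio scale), robust to one bad quantification; ``n_merged`` counts the
    collapsed rows.  Distinct site annotations under one protein key are kept
    as separate records with a warning, never averaged together.
    """
    key = _site_key_columns(records)
    if len(key) > 2 and len(records):
        per_protein = (records.drop_duplicates(subset=key)
                       .groupby(["gene_names", "proteins"]).size())
        n_conflict = int((per_protein > 1).sum())
        if n_conflict:
            warnings.warn(
                f"{n_conflict} (gene, protein) key(s) carry distinct site "
                "annotations; kept as separate records"
            )
    if not records.duplicated(subset=key).any():
        out = records.copy()
        out["n_merged"] = 1
        return out

    def _merge(group: pd.DataFrame) -> pd.Series:
        row = group.iloc[0].copy()
        ratios = group["ratio_hl"].dropna()
        row["ratio_hl"] = (
            float(2.0 ** np.median(np.log2(ratios))) if len(ratios) else np.nan
        )
        if "localization_prob" in group.columns:
            row["localization_prob"] = group["localization_prob"].max()
        row["n_merged"] = len(group)
        return row

    merged = (records.groupby(key, dropna=False, sort=False)
              .apply(_merge, include_groups=False))
    merged = merged.reset_index()
    return merged[[*records.columns, "n_merged"]]


# ---------------------------------------------------------------------------
# normalization, orientation, significance
# ---------------------------------------------------------------------------


def normalize_and_orient(records: pd.DataFrame, mutant_channel_forward: str,
                         orientation: str = "forward",
                         center: str = "median") -> pd.DataFrame:
    """Log2-transform, orient and center one replicate's H/L ratios.

    ``mutant_channel_forward`` ("heavy" or "light") names the SILAC channel
    carrying the mutant condition in the *forward* experiment; the reverse
    replicate is assumed label-swapped, so its sign is flipped.  After
    orientation, positive values mean higher in the mutant.  Centering
    subtracts the median (default) or mean of the oriented non-missing
    values; the center used is stored in ``frame.attrs["center"]``.
    """
    if mutant_channel_forward not in {"heavy", "light"}:
        raise ValueError("mutant_channel_forward must be 'heavy' or 'light'")
    if orientation not in {"forward", "reverse"}:
        raise ValueError("orientation must be 'forward' or 'reverse'")
    if center not in {"median", "mean"}:
        raise ValueError("center must be 'median' or 'mean'")
    ratios = records["ratio_hl"]
    if (ratios.dropna() <= 0).any():
        raise ValueError("non-positive ratio; parse_table should have caught this")

    sign = 1.0 if mutant_channel_forward == "heavy" else -1.0
    if orientation == "reverse":
        sign = -sign
    oriented = sign * np.log2(ratios.astype(float))
    observed = oriented.dropna()
    c = float(observed.median() if center == "median" else observed.mean())

    out = records.copy()
    out["log2c"] = oriented - c
    out.attrs["center"] = c
    out.attrs["orientation"] = orientation
    return out


def flag_significant(values: Sequence[float] | np.ndarray,
                     exclude: np.ndarray | None = None,
                     n_sd: float = 2.0) -> tuple[np.ndarray, dict[str, float]]:
    """Flag centered log2 ratios beyond ``mean +/- n_sd * SD``.

    The mean and sample SD are computed over non-missing values not marked in
    ``exclude`` (e.g. imputed entries); excluded entries are never flagged.
    Requires at least 3 usable values; zero spread flags nothing, with a
    warning.  Returns the boolean flags and the threshold statistics.
    """
    v = np.asarray(values, dtype=float)
    use = np.isfinite(v)
    if exclude is not None:
        use &= ~np.asarray(exclude, dtype=bool)
    if use.sum() < 3:
        raise ValueError("need at least 3 non-missing, non-imputed values")
    mean = float(v[use].mean())
    sd = float(v[use].std(ddof=1))
    stats = {"mean": mean, "sd": sd,
             "lower": mean - n_sd * sd, "upper": mean + n_sd * sd}
    flags = np.zeros(v.shape, dtype=bool)
    if sd == 0:
        warnings.warn("zero spread among usable values; nothing flagged")
        return flags, stats
    flags[use] = (v[use] < stats["lower"]) | (v[use] > stats["upper"])
    return flags, stats


def impute_missing(values: Sequence[float] | np.ndarray,
                   constant: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Impute missing centered log2 ratios for display.

    Missing entries become ``min(observed) - constant`` (log2 units) and are
    flagged; imputed values exist to make missingness visible in plots and
    must never enter SD estimation or significance calling.
    """
    v = np.asarray(values, dtype=float)
    observed = v[np.isfinite(v)]
    if observed.size == 0:
        raise ValueError("cannot impute: no observed values")
    imputed = ~np.isfinite(v)
    out = v.copy()
    out[imputed] = observed.min() - constant
    return out, imputed


def combine_replicates(forward: pd.DataFrame, reverse: pd.DataFrame,
                       n_sd: float = 2.0) -> pd.DataFrame:
    """Combine oriented forward/reverse replicates site-by-site.

    The combined value is the mean of the available oriented centered log2
    ratios.  Sites quantified in only one replicate are flagged
    ``single_replicate``.  Sites where the replicates disagree in sign and
    each exceeds ``n_sd`` times its replicate's SD are flagged ``discordant``
    and are excluded from significance calling downstream.
    """
    key = _site_key_columns(forward)
    f = forward[[*key, "log2c"]].rename(columns={"log2c": "log2c_forward"})
    r = reverse[[*key, "log2c"]].rename(columns={"log2c": "log2c_reverse"})
    merged = f.merge(r, on=key, how="outer")

    lf = merged["log2c_forward"].to_numpy(dtype=float)
    lr = merged["log2c_reverse"].to_numpy(dtype=float)
    n_obs = np.isfinite(lf).astype(int) + np.isfinite(lr).astype(int)
    total = np.where(np.isfinite(lf), lf, 0.0) + np.where(np.isfinite(lr), lr, 0.0)
    merged["log2c_combined"] = np.where(n_obs > 0, total / np.maximum(n_obs, 1), np.nan)
    merged["single_replicate"] = n_obs == 1

    sd_f = float(np.nanstd(lf, ddof=1))
    sd_r = float(np.nanstd(lr, ddof=1))
    both = np.isfinite(lf) & np.isfinite(lr)
    with np.errstate(invalid="ignore"):
        merged["discordant"] = (
            both & (np.sign(lf) * np.sign(lr) < 0)
            & (np.abs(lf) > n_sd * sd_f) & (np.abs(lr) > n_sd * sd_r)
        )
    return merged


def differential_analysis(forward: pd.DataFrame, reverse: pd.DataFrame,
                          mutant_channel_forward: str,
                          min_unique: int = 2, min_loc_prob: float = 0.75,
                          center: str = "median", n_sd: float = 2.0,
                          impute_constant: float = 0.1
                          ) -> tuple[pd.DataFrame, dict]:
    """Full per-table-pair differential chain; returns results and a log dict.

    Filtering and duplicate merging run per replicate; orientation and
    centering are per replicate; significance is called on the combined
    oriented values, never on imputed or discordant entries.  The
    ``log2c_display`` column carries imputed values for visualization.
    """
    info: dict = {}
    reps = {}
    for name, table in (("forward", forward), ("reverse", reverse)):
        kept, drops = filter_records(table, min_unique=min_unique,
                                     min_loc_prob=min_loc_prob)
        merged = merge_duplicates(kept)
        oriented = normalize_and_orient(merged, mutant_channel_forward,
                                        orientation=name, center=center)
        info[name] = {"input_rows": len(table), "dropped": drops,
                      "kept": len(kept), "center": oriented.attrs["center"]}
        reps[name] = oriented

    combined = combine_replicates(reps["forward"], reps["reverse"], n_sd=n_sd)
    values = combined["log2c_combined"].to_numpy(dtype=float)
    usable = np.isfinite(values) & ~combined["discordant"].to_numpy(bool)
    flags, stats = flag_significant(values, exclude=~usable, n_sd=n_sd)
    combined["significant"] = flags
    display, imputed = impute_missing(values, constant=impute_constant)
    combined["log2c_display"] = display
    combined["imputed"] = imputed
    info["combined"] = {"n_sites": len(combined), **stats,
                        "n_significant": int(flags.sum()),
                        "n_discordant": int(combined["discordant"].sum()),
                        "n_imputed": int(imputed.sum())}
    return combined, info


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


def hypergeom_tail_p(overlap: int, background: int, set_size: int,
                     n_significant: int) -> float:
    """Upper-tail hypergeometric p: P(X >= overlap) drawing ``n_significant``
    genes from ``background`` of which ``set_size`` are in the set.

    This is the one-sided Fisher's exact over-representation p-value of the
    corresponding 2x2 table.
    """
    if not 0 <= set_size <= background or not 0 <= n_significant <= background:
        raise ValueError("set_size and n_significant must lie in [0, background]")
    return float(sps.hypergeom.sf(overlap - 1, background, set_size,
                                  n_significant))


def fisher_enrichment(significant_genes: Iterable[str],
                      background_genes: Iterable[str],
                      gene_sets: Mapping[str, Iterable[str]] | str | Path
                      ) -> pd.DataFrame:
    """One-sided over-representation of each gene set among significant genes.

    Each set is intersected with the background before testing.  The p-value
    is the hypergeometric upper tail P(X >= overlap) of the 2x2 table
    (equivalently one-sided Fisher's exact test); Benjamini-Hochberg adjusted
    p-values are reported across sets, alongside the sample odds ratio.
    """
    if isinstance(gene_sets, (str, Path)):
        gene_sets = read_gmt(gene_sets)
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene list")
    significant = set(significant_genes)
    if not significant <= background:
        raise ValueError("significant genes must be a subset of the background")

    M = len(background)
    N = len(significant)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & background
        K = len(in_bg)
        k = len(in_bg & significant)
        p = hypergeom_tail_p(k, M, K, N)
        a, b = k, N - k
        c, d = K - k, M - N - (K - k)
        if b * c > 0:
            odds = (a * d) / (b * c)
        else:
            odds = np.inf if a * d > 0 else np.nan
        rows.append({"set_name": name, "overlap": k, "set_size": K,
                     "background_size": M, "odds_ratio": odds, "p": p})
    result = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                         "background_size", "odds_ratio", "p"])
    if len(result):
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result.sort_values("p", kind="stable").reset_index(drop=True)
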