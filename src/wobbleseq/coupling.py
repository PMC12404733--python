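"""I34-abundance coupling and ADAT-dependent codon enrichment.

Two permutation statistics close the analysis:

* **Coupling** -- the Spearman rank correlation between per-unit I34 change
  and abundance change (both case-minus-control, log2 scale).  With this sign
  convention a *positive* r means greater I34 loss accompanies greater
  abundance loss.  Significance comes from unit-label permutation with the
  add-one rule, so p is never exactly 0.

* **Enrichment** -- whether a gene set's mean usage share of an ADAT-dependent
  codon (within its synonymous decoded box) exceeds that of random same-size
  gene sets drawn from the background universe, optionally length-matched by
  CDS-length decile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import (
    AnticodonFamily,
    CodonSet,
    classify_adat_targets,
    enumerate_dependent_codons,
    packaged_anticodon_table,
    to_rna,
)


@dataclass
class CouplingResult:
    n: int
    r: float
    p: float
    table: pd.DataFrame


def spearman_coupling(
    delta_i34: pd.Series,
    delta_abundance: pd.Series,
    B: int = 10_000,
    seed: int = 0,
    annotations: pd.DataFrame | None = None,
) -> CouplingResult:
    """Spearman correlation of matched per-unit deltas with a permutation p.

    p = (1 + #{|r*| >= |r|}) / (1 + B) under random permutation of one
    vector's unit labels (two-sided).  Ties receive average ranks.
    """
    units = sorted(set(delta_i34.index) & set(delta_abundance.index))
    if len(units) < 5:
        raise ValueError(f"need >= 5 matched units, got {len(units)}")
    x = delta_i34.reindex(units).to_numpy(dtype=float)
    y = delta_abundance.reindex(units).to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant delta vector: Spearman r undefined")
    r = float(stats.spearmanr(x, y).statistic)

    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    # r* of a permutation is the mean product of standardized ranks
    perms = np.stack([rng.permutation(ry) for _ in range(B)])
    r_null = perms @ rx / len(units)
    p = (1.0 + int(np.sum(np.abs(r_null) >= abs(r) - 1e-12))) / (1.0 + B)

    table = pd.DataFrame(
        {"delta_i34_log2": x, "delta_abundance_log2": y}, index=units
    )
    if annotations is not None:
        table = table.join(annotations, how="left")
    return CouplingResult(n=len(units), r=r, p=float(p), table=table)


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

def _family_codon_sets(
    anticodon_table: pd.DataFrame | None = None,
) -> dict[str, CodonSet]:
    table = anticodon_table if anticodon_table is not None else packaged_anticodon_table()
    out = {}
    for fam in classify_adat_targets(table):
        out[fam.label] = enumerate_dependent_codons(fam, table)
    return out


def codon_usage(
    cds: dict[str, str],
    codon_sets: dict[str, CodonSet] | None = None,
) -> pd.DataFrame:
    """Per-gene dependent-codon usage shares.

    For each gene and ADAT family: the count of the family's dependent codon
    and of all codons in the family's decoded box (the synonymous codons the
    I34 anticodon reads), with share = dependent / box.  Genes whose length is
    not a multiple of 3 or that contain an internal stop are skipped and
    listed in ``result.attrs['skipped']``.  Genes without codons of a box get
    NaN for that family (excluded from its test).
    """
    sets = codon_sets if codon_sets is not None else _family_codon_sets()
    stops = {"TAA", "TAG", "TGA"}

    def codon_code(codon: str) -> int:
        return sum("ACGT".index(b) * 4**k for k, b in enumerate(reversed(codon)))

    stop_codes = {codon_code(c) for c in stops}
    skipped: list[tuple[str, str]] = []
    genes: list[str] = []
    hists: list[np.ndarray] = []
    base_code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        base_code[ord(b)] = i
    base_code[ord("U")] = base_code[ord("T")]
    for gene, seq in cds.items():
        if len(seq) % 3 != 0:
            skipped.append((gene, "length not a multiple of 3"))
            continue
        arr = base_code[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        codes = arr.reshape(-1, 3) @ np.array([16, 4, 1])
        codes = codes[(arr.reshape(-1, 3) >= 0).all(axis=1)]
        if len(codes) and int(codes[-1]) in stop_codes:
            codes = codes[:-1]
        if np.isin(codes, list(stop_codes)).any():
            skipped.append((gene, "internal stop codon"))
            continue
        genes.append(gene)
        hists.append(np.bincount(codes, minlength=64))
    if genes:
        H = np.stack(hists)
        data: dict[str, np.ndarray] = {"n_codons": H.sum(axis=1)}
        for fam, cs in sets.items():
            box = H[:, [codon_code(c) for c in cs.decoded_codons]].sum(axis=1)
            dep = H[:, [codon_code(c) for c in cs.dependent_codons]].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                share = np.where(box > 0, dep / np.maximum(box, 1), np.nan)
            data[f"{fam}:box"] = box
            data[f"{fam}:dependent"] = dep
            data[f"{fam}:share"] = share
        out = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    else:
        out = pd.DataFrame()
    out.attrs["skipped"] = skipped
    out.attrs["families"] = sorted(sets)
    return out


# ---------------------------------------------------------------------------
# enrichment test
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    family: str
    dependent_codon: str
    n_genes: int
    observed_share: float
    background_share: float
    p: float
    B: int


def _null_means(
    shares: np.ndarray, set_size: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of B random size-*set_size* subsets drawn without replacement."""
    n = len(shares)
    out = np.empty(B)
    for b in range(B):
        out[b] = shares[rng.choice(n, set_size, replace=False)].mean()
    return out


def enrichment_test(
    geneset_ids,
    usage: pd.DataFrame,
    family: str,
    B: int = 10_000,
    seed: int = 0,
    length_match: bool = False,
    two_sided: bool = False,
    codon_sets: dict[str, CodonSet] | None = None,
) -> EnrichmentResult:
    """Permutation test of dependent-codon usage in a gene set.

    Statistic: mean usage share over the gene set.  Null: B random gene sets
    of the same size drawn from the background universe (all genes in
    *usage*), length-matched by CDS-length decile when requested.  One-sided
    (usage higher in set) by default; p uses the add-one rule.
    """
    if B < 1000:
        raise ValueError("B must be >= 1000")
    col = f"{family}:share"
    if col not in usage.columns:
        raise ValueError(f"unknown family {family!r}")
    geneset = sorted(set(geneset_ids))
    missing = set(geneset) - set(usage.index)
    if missing:
        raise ValueError(f"gene set members absent from background: {sorted(missing)[:5]}")

    valid = usage[usage[col].notna()]
    in_set = valid.index.isin(geneset)
    set_shares = valid.loc[in_set, col].to_numpy(dtype=float)
    if len(set_shares) < 5:
        raise ValueError(f"gene set has fewer than 5 genes with {family} codons")
    observed = float(set_shares.mean())
    rng = np.random.default_rng(seed)

    if length_match:
        deciles = pd.qcut(valid["n_codons"], 10, labels=False, duplicates="drop")
        null = np.zeros(B)
        total = 0
        for d in np.unique(deciles[in_set]):
            stratum = valid.loc[deciles == d, col].to_numpy(dtype=float)
            k = int((deciles[in_set] == d).sum())
            if k == 0:
                continue
            null += _null_means(stratum, min(k, len(stratum)), B, rng) * k
            total += k
        null /= max(total, 1)
    else:
        null = _null_means(
            valid[col].to_numpy(dtype=float), len(set_shares), B, rng
        )

    if two_sided:
        centre = float(null.mean())
        exceed = np.sum(np.abs(null - centre) >= abs(observed - centre) - 1e-15)
    else:
        exceed = np.sum(null >= observed - 1e-15)
    p = (1.0 + int(exceed)) / (1.0 + B)

    sets = codon_sets if codon_sets is not None else _family_codon_sets()
    dep = sets[family].dependent_codons if family in sets else ()
    return EnrichmentResult(
        family=family,
        dependent_codon=to_rna(dep[0]) if dep else "",
        n_genes=len(set_shares),
        observed_share=observed,
        background_share=float(valid[col].mean()),
        p=float(p),
        B=B,
    )


def enrichment_summary(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate per-family enrichment with significance bands at p < 0.05
    (significant) and p < 0.1 (trending)."""
    rows = []
    for r in results:
        band = "significant" if r.p < 0.05 else ("trending" if r.p < 0.1 else "ns")
        rows.append(
            {
                "family": r.family,
                "dependent_codon": r.dependent_codon,
                "n_genes": r.n_genes,
                "observed_share": r.observed_share,
                "background_share": r.background_share,
                "p": r.p,
                "band": band,
            }
        )
    return pd.DataFrame(rows)
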