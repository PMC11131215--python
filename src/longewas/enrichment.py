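"""Hypergeometric over-representation of genes (or probes) in user-supplied sets.

With universe size N, function-set size M, marker list size R and overlap k,
the default enrichment p is the upper hypergeometric tail P(X >= k) — the
standard one-sided Fisher test for over-representation. A second convention,
``paper_gt``, computes P(X > k) = 1 - sum_{i=0}^{k} of the hypergeometric
mass, which excludes the observed overlap itself (and so returns 0 at full
overlap); it is provided because some write-ups print the formula that way.
The exact relation p_geq(k) = p_gt(k - 1) holds for k >= 1.

Gene sets are read from GMT files (set id, description, members, tab
separated). No live ontology queries: collections are plain files so the
test suite fully controls N, M, R and k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import EnrichmentQuery, ValidationError
from .longitudinal_ewas import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional explicit universe.

    ``sets`` maps set id to (description, members). When a universe is given
    it must contain every member of every set.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValidationError("collection contains no gene sets")
        if self.universe is not None:
            for sid, (_, members) in self.sets.items():
                extra = members - self.universe
                if extra:
                    raise ValidationError(
                        f"set {sid!r} has members outside the universe: {sorted(extra)[:5]}")

    @property
    def set_ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line (need id, description, >=1 member): {line[:80]!r}")
        sid, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if sid in sets:
            raise ValidationError(f"duplicate set id {sid!r} in {path}")
        sets[sid] = (desc, frozenset(members))
    return GeneSetCollection(sets=sets, universe=None if universe is None else frozenset(universe))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([sid, desc, *sorted(members)])
        for sid, (desc, members) in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def annotate_cpgs_to_genes(probes: Sequence[str], manifest: pd.DataFrame) -> list[str]:
    """Unique gene labels annotated to the probes (sorted; empty annotations skipped).

    Multi-gene annotations are split on ';' with surrounding whitespace
    stripped.
    """
    missing = [p for p in probes if p not in manifest.index]
    if missing:
        raise ValidationError(f"probes absent from manifest: {missing[:5]}")
    genes: set[str] = set()
    for raw in manifest.loc[list(probes), "gene"]:
        for g in str(raw).split(";"):
            g = g.strip()
            if g:
                genes.add(g)
    return sorted(genes)


def hypergeometric_enrichment(query: EnrichmentQuery, tail: str = "geq") -> float:
    """Enrichment p for one query under the chosen tail convention.

    ``geq``: P(X >= k) (the default over-representation tail);
    ``paper_gt``: P(X > k), the literal 1 - sum_{i<=k} form.
    """
    n, m, r, k = query.universe_size, query.set_size, query.marker_size, query.overlap
    if tail == "geq":
        return float(stats.hypergeom.sf(k - 1, n, m, r))
    if tail == "paper_gt":
        return float(stats.hypergeom.sf(k, n, m, r))
    raise ValidationError(f"unknown tail {tail!r}; expected 'geq' or 'paper_gt'")


def enrich_gene_list(
    genes: Sequence[str],
    collection: GeneSetCollection,
    universe_size_override: int | None = None,
    tail: str = "geq",
) -> pd.DataFrame:
    """Per-set enrichment table (set_id, N, M, R, k, p_value, fdr), sorted by p.

    The universe is the collection's explicit universe; genes and set members
    are intersected with it. Without an explicit universe a
    ``universe_size_override`` is required (the choice of N is substantive
    and is therefore never guessed).
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("gene list is empty")
    if collection.universe is not None:
        universe = collection.universe
        n = universe_size_override or len(universe)
        markers = gene_set & universe
        if not markers:
            raise ValidationError("no genes from the list fall inside the universe")
    elif universe_size_override is not None:
        universe = None
        n = int(universe_size_override)
        markers = gene_set
    else:
        raise ValidationError(
            "collection has no explicit universe; pass universe_size_override")
    rows = []
    for sid, (desc, members) in collection.sets.items():
        mem = members if universe is None else (members & universe)
        k = len(markers & mem)
        q = EnrichmentQuery(universe_size=n, set_size=len(mem),
                            marker_size=len(markers), overlap=k)
        rows.append({"set_id": sid, "description": desc, "N": n, "M": len(mem),
                     "R": len(markers), "k": k,
                     "p_value": hypergeometric_enrichment(q, tail=tail)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)


def tfbs_enrichment(
    probes: Sequence[str],
    tfbs_annotation: Mapping[str, Sequence[str]],
    tail: str = "geq",
) -> pd.DataFrame:
    """Transcription-factor binding-site enrichment with probes as the unit.

    ``tfbs_annotation`` maps every probe of the universe to the transcription
    factors binding it (possibly empty). The machinery is identical to
    :func:`enrich_gene_list` with TF -> bound-probe sets as the collection
    and the annotation's keys as the universe.
    """
    universe = frozenset(tfbs_annotation)
    selected = set(probes)
    outside = selected - universe
    if outside:
        raise ValidationError(f"probes missing from the TFBS annotation: {sorted(outside)[:5]}")
    by_tf: dict[str, set[str]] = {}
    for probe, tfs in tfbs_annotation.items():
        for tf in tfs:
            by_tf.setdefault(tf, set()).add(probe)
    if not by_tf:
        raise ValidationError("TFBS annotation names no transcription factors")
    collection = GeneSetCollection(
        sets={tf: (f"probes bound by {tf}", frozenset(ps)) for tf, ps in sorted(by_tf.items())},
        universe=universe,
    )
    out = enrich_gene_list(sorted(selected), collection, tail=tail)
    return out.rename(columns={"set_id": "tf"})
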