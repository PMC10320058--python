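"""Self-contained synthetic inputs with known ground truth.

A fixture is a directory of desk-scale stand-ins for the real
knowledgebase sources: a random-DAG OBO ontology, a GAF with a controlled
evidence-code mix, pathway-style GMT sets, an RPKM expression matrix with
genes planted to satisfy the tissue-preference rule in exactly one group,
a genotype–phenotype table with known single-allele records, an id-mapping
table, and input gene lists with planted overlap.  A ground-truth JSON
records every planted fact (computed with independent closed forms /
brute-force closures, not with the package's analysis code), and a
manifest records the SHA256 of every file — identical seeds yield
byte-identical fixtures.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

EXPERIMENTAL_CODES = ("EXP", "IDA", "IMP", "IGI", "IPI", "IEP")
COMPUTATIONAL_CODES = ("IEA", "IBA", "ISS", "ISO", "RCA")
HTP_CODES = ("HTP", "HDA", "HMP", "HGI", "HEP")

TOY_SET_ID = "TOY:S1"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture; identical seeds reproduce bytes."""

    seed: int = 0
    n_genes: int = 60
    n_terms: int = 20
    dag_depth: int = 4
    n_tissue_groups: int = 3
    n_planted_specific: int = 5
    #: proportions of (experimental, computational, HTP) evidence codes
    evidence_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    #: (pathway set id, overlap fraction) pairs driving list generation
    planted_enrichment: tuple[tuple[str, float], ...] = (("PWY:0001", 0.8),)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_terms", "dag_depth", "n_tissue_groups",
                     "n_planted_specific"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if abs(sum(self.evidence_mix) - 1.0) > 1e-9:
            raise ConfigurationError("evidence_mix proportions must sum to 1")
        if self.dag_depth < 2:
            raise ConfigurationError("dag_depth must be >= 2")
        if self.n_planted_specific > self.n_genes:
            raise ConfigurationError("n_planted_specific exceeds n_genes")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _closure(parents: dict[str, list[str]]) -> dict[str, set[str]]:
    """Brute-force ancestor closure by repeated expansion (oracle-grade)."""
    anc = {t: set(ps) for t, ps in parents.items()}
    changed = True
    while changed:
        changed = False
        for t in anc:
            add = set()
            for p in anc[t]:
                add |= anc.get(p, set())
            if not add <= anc[t]:
                anc[t] |= add
                changed = True
    return anc


def _upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric by combinatorial sum (math.comb)."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(n, K) + 1)) / total


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write all fixture files into ``out_dir``; return the manifest dict.

    The manifest (also written as ``manifest.json``) maps each relative
    file name to its SHA256.  ``ground_truth.json`` records the planted
    facts each analysis module is expected to recover.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"seed": spec.seed}

    genes = [f"FBgn{8000001 + i:07d}" for i in range(spec.n_genes)]
    symbols = {g: f"sym{i:03d}" for i, g in enumerate(genes)}

    # -- ontology ------------------------------------------------------
    terms = [f"GO:{1000001 + i:07d}" for i in range(spec.n_terms)]
    layer = {terms[0]: 0}
    parents: dict[str, list[tuple[str, str]]] = {terms[0]: []}
    for t in terms[1:]:
        layer[t] = int(rng.integers(1, spec.dag_depth))
        lower = [u for u in terms if u in layer and layer[u] < layer[t] and u != t]
        n_par = int(rng.integers(1, 3)) if len(lower) > 1 else 1
        chosen = sorted(rng.choice(len(lower), size=min(n_par, len(lower)),
                                   replace=False).tolist())
        parents[t] = [
            (lower[i], "part_of" if rng.random() < 0.2 else "is_a") for i in chosen
        ]
    alt_term, alt_id = terms[min(1, spec.n_terms - 1)], "GO:0999999"
    obsolete_term = "GO:0900001"

    obo_lines = ["format-version: 1.2", "ontology: synthetic-bp", ""]
    for t in terms:
        obo_lines += [f"[Term]", f"id: {t}", f"name: synthetic term {t[-4:]}",
                      "namespace: biological_process"]
        if t == alt_term:
            obo_lines.append(f"alt_id: {alt_id}")
        for pid, rel in parents[t]:
            if rel == "is_a":
                obo_lines.append(f"is_a: {pid} ! parent")
            else:
                obo_lines.append(f"relationship: part_of {pid} ! parent")
        obo_lines.append("")
    obo_lines += ["[Term]", f"id: {obsolete_term}", "name: retired synthetic term",
                  "namespace: biological_process", "is_obsolete: true", ""]
    (out / "ontology.obo").write_text("\n".join(obo_lines))

    # -- GAF with controlled evidence mix ------------------------------
    p_exp, p_comp, p_htp = spec.evidence_mix
    planted_iea_pair = (genes[0], terms[-1])
    planted_hda_pair = (genes[1], terms[-2] if spec.n_terms > 1 else terms[-1])
    not_row_pair = (genes[2 % spec.n_genes], terms[0])

    annotations: list[tuple[str, str, str, str]] = []  # gene, term, code, qualifier
    for g in genes:
        n_ann = int(rng.integers(1, 4))
        picks = rng.choice(spec.n_terms, size=min(n_ann, spec.n_terms), replace=False)
        for idx in sorted(picks.tolist()):
            t = terms[idx]
            if (g, t) in (planted_iea_pair, planted_hda_pair, not_row_pair):
                continue
            cls = rng.choice(3, p=[p_exp, p_comp, p_htp])
            pool = (EXPERIMENTAL_CODES, COMPUTATIONAL_CODES, HTP_CODES)[cls]
            code = pool[int(rng.integers(0, len(pool)))]
            annotations.append((g, t, code, "involved_in"))
    annotations.append((*planted_iea_pair, "IEA", "involved_in"))
    annotations.append((*planted_hda_pair, "HDA", "involved_in"))
    annotations.append((*not_row_pair, "IDA", "NOT|involved_in"))
    annotations.sort()

    gaf_lines = ["!gaf-version: 2.2"]
    for g, t, code, qual in annotations:
        gaf_lines.append("\t".join([
            "FB", g, symbols[g], qual, t, "FB:FBrf0000001", code, "", "P",
            f"synthetic gene {symbols[g]}", "", "protein", "taxon:7227",
            "20230101", "FlyBase", "", "",
        ]))
    (out / "annotations.gaf").write_text("\n".join(gaf_lines) + "\n")

    # ground truth: pair-level evidence survivors (independent of the
    # package's filter implementation)
    pair_codes: dict[tuple[str, str], set[str]] = {}
    for g, t, code, qual in annotations:
        if "NOT" in qual.split("|"):
            continue
        pair_codes.setdefault((g, t), set()).add(code)
    comp, htp = set(COMPUTATIONAL_CODES), set(HTP_CODES)
    survivors_exp = {p for p, c in pair_codes.items() if not c <= comp}
    survivors_htp = {p for p, c in pair_codes.items() if not c <= htp}
    truth["evidence"] = {
        "n_pairs_all": len(pair_codes),
        "n_pairs_experimental_only": len(survivors_exp),
        "n_pairs_exclude_htp_only": len(survivors_htp),
        "planted_iea_pair": list(planted_iea_pair),
        "planted_hda_pair": list(planted_hda_pair),
        "not_row_pair": list(not_row_pair),
    }

    # ground truth: direct and propagated set sizes (brute-force closure)
    anc = _closure({t: [p for p, _ in parents[t]] for t in terms})
    direct: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    for (g, t) in pair_codes:
        direct.setdefault(t, set()).add(g)
        for tt in {t} | anc[t]:
            propagated.setdefault(tt, set()).add(g)
    truth["go_sets"] = {
        "direct_sizes": {t: len(m) for t, m in sorted(direct.items())},
        "propagated_sizes": {t: len(m) for t, m in sorted(propagated.items())},
    }

    # -- pathway GMT ----------------------------------------------------
    pathway_sets: dict[str, list[str]] = {}
    for i in range(5):
        size = int(rng.integers(6, 13))
        picks = sorted(rng.choice(spec.n_genes, size=min(size, spec.n_genes),
                                  replace=False).tolist())
        pathway_sets[f"PWY:{i + 1:04d}"] = [genes[j] for j in picks]
    gmt_lines = [
        "\t".join([sid, f"synthetic pathway {sid}", *members])
        for sid, members in sorted(pathway_sets.items())
    ]
    (out / "pathways.gmt").write_text("\n".join(gmt_lines) + "\n")
    pathway_universe = sorted({g for m in pathway_sets.values() for g in m})

    # -- planted enrichment lists ---------------------------------------
    truth["enrichment_lists"] = {}
    for sid, frac in spec.planted_enrichment:
        if sid not in pathway_sets:
            raise ConfigurationError(f"planted_enrichment names unknown set {sid!r}")
        members = pathway_sets[sid]
        k = max(1, round(frac * len(members)))
        inside = [members[i] for i in
                  sorted(rng.choice(len(members), size=k, replace=False).tolist())]
        outside_pool = [g for g in pathway_universe if g not in members]
        n_out = min(3, len(outside_pool))
        outside = [outside_pool[i] for i in
                   sorted(rng.choice(len(outside_pool), size=n_out, replace=False).tolist())]
        listed = inside + outside
        fname = f"list_{sid.replace(':', '_')}.txt"
        (out / fname).write_text(
            "# planted enrichment list for " + sid + "\n" + "\n".join(listed) + "\n"
        )
        N, K, n = len(pathway_universe), len(members), len(listed)
        truth["enrichment_lists"][sid] = {
            "file": fname, "N": N, "K": K, "n": n, "k": k,
            "p_upper_tail": _upper_tail(N, K, n, k),
            "fold_enrichment": (k / n) / (K / N),
        }

    # -- toy enumeration example ----------------------------------------
    toy_genes = [f"TOY{i + 1:03d}" for i in range(10)]
    (out / "toy_sets.gmt").write_text(
        "\t".join([TOY_SET_ID, "toy marked set", *toy_genes[:5]]) + "\n"
        + "\t".join(["TOY:ALL", "toy universe", *toy_genes]) + "\n"
    )
    (out / "toy_list.txt").write_text("\n".join(toy_genes[:4]) + "\n")
    truth["toy_example"] = {
        "N": 10, "K": 5, "n": 4, "k": 4,
        "p_upper_tail": _upper_tail(10, 5, 4, 4),  # 5/210
        "fold_enrichment": 2.0,
    }

    # -- expression matrix with planted tissue-specific genes -----------
    groups = [f"tg{i + 1:02d}" for i in range(spec.n_tissue_groups)]
    samples = [(f"{g}_r{r}", g) for g in groups for r in (1, 2)]
    planted_idx = sorted(rng.choice(spec.n_genes, size=spec.n_planted_specific,
                                    replace=False).tolist())
    planted_group = {
        genes[i]: groups[int(rng.integers(0, len(groups)))] for i in planted_idx
    }
    rows = []
    for i, g in enumerate(genes):
        if g in planted_group:
            vals = [
                rng.uniform(80.0, 120.0) if grp == planted_group[g]
                else rng.uniform(0.5, 3.0)
                for _s, grp in samples
            ]
        else:
            base = rng.uniform(1.0, 40.0)
            vals = [base * rng.uniform(0.9, 1.1) for _ in samples]
        rows.append((g, vals))
    header = "gene_id\t" + "\t".join(s for s, _ in samples)
    body = [g + "\t" + "\t".join(format(v, ".4f") for v in vals) for g, vals in rows]
    (out / "expression.tsv").write_text(header + "\n" + "\n".join(body) + "\n")
    (out / "sample_groups.tsv").write_text(
        "sample\ttissue_group\n"
        + "\n".join(f"{s}\t{grp}" for s, grp in samples) + "\n"
    )
    truth["tissue"] = {"planted": dict(sorted(planted_group.items()))}

    # -- genotype-phenotype table ---------------------------------------
    phenos = [f"FBcv:{i + 1:07d}" for i in range(4)]
    gx = [genes[i % spec.n_genes] for i in range(10)]
    gp_rows = [
        (f"{symbols[gx[0]]}[1]", gx[0], "classical", phenos[0]),
        (f"{symbols[gx[1]]}[EP1]", gx[1], "insertional", phenos[0]),
        (f"{symbols[gx[2]]}[1] {symbols[gx[3]]}[2]",
         f"{gx[2]}|{gx[3]}", "classical", phenos[1]),
        (f"Scer\\GAL4[da.G32] {symbols[gx[4]]}[UAS]", gx[4], "other", phenos[1]),
        (f"{symbols[gx[5]]}[2]", gx[5], "classical", phenos[1]),
        (f"{symbols[gx[6]]}[j5B4]", gx[6], "insertional", phenos[2]),
        (f"{symbols[gx[7]]}[1]/{symbols[gx[8]]}[Df]",
         f"{gx[7]}|{gx[8]}", "other", phenos[2]),
        (f"{symbols[gx[9]]}[3]", gx[9], "classical", phenos[3]),
    ]
    (out / "genotype_phenotype.tsv").write_text(
        "genotype\tgene_ids\tallele_class\tphenotype_term_id\n"
        + "\n".join("\t".join(r) for r in gp_rows) + "\n"
    )
    expected_pheno: dict[str, list[str]] = {}
    for _gt, gid, cls, ph in gp_rows:
        gs = gid.split("|")
        if len(gs) == 1 and cls in ("classical", "insertional"):
            expected_pheno.setdefault(ph, []).append(gs[0])
    truth["phenotype_sets"] = {
        ph: sorted(set(ms)) for ph, ms in sorted(expected_pheno.items())
    }

    # -- id mapping table ------------------------------------------------
    id_rows = [("wg", "FBgn0284084", "symbol"),
               ("wingless", "FBgn0284084", "fullname"),
               ("WNT1", "HGNC:12774", "symbol")]
    for i, g in enumerate(genes):
        id_rows.append((symbols[g], g, "symbol"))
        if i < 5:
            id_rows.append((f"FBgn{7000001 + i:07d}", g, "secondary"))
    # a deliberately ambiguous alias hitting two canonical ids
    id_rows.append(("ambig1", genes[0], "symbol"))
    id_rows.append(("ambig1", genes[1], "symbol"))
    (out / "id_map.tsv").write_text(
        "alias\tcanonical_id\talias_type\n"
        + "\n".join("\t".join(r) for r in id_rows) + "\n"
    )
    truth["id_map"] = {
        "examples": {"wg": "FBgn0284084", "WNT1": "HGNC:12774"},
        "ambiguous_alias": "ambig1",
        "secondary_ids": {f"FBgn{7000001 + i:07d}": genes[i] for i in range(5)},
    }

    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
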