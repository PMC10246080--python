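"""Seeded synthetic fixtures: toy ontologies, annotations, gene sets.

Every other module is testable offline against these generators. A fixture
is a layered random DAG of labeled terms (optionally with synonyms and
obsolete terms), gene→term annotations with one "planted" over-represented
term that annotates the sample at a much higher rate than the background,
a gene set drawn from that sample, and a narrative description table whose
texts embed the annotation labels (so the deterministic mock model can
solve the task from narrative as well as ontological descriptions).

Everything is reproducible from the spec's seed, and the on-disk forms
(OBO, GAF 2.2, gene set YAML, narrative TSV) round-trip through the
package's own readers.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .annotations import GeneAnnotationStore, GeneSet, load_gaf, load_gene_set, write_gene_set
from .descriptions import load_narrative_table, write_narrative_table
from .errors import FixtureSpecError
from .ontology import Ontology, OntologyTerm, load_ontology

_ADJECTIVES = [
    "apical", "basal", "cortical", "distal", "dorsal", "ventral", "lateral",
    "medial", "proximal", "radial", "axial", "polar", "fibrous", "granular",
    "vesicular", "tubular", "lamellar", "nodal", "septal", "villous",
    "ciliary", "flagellar", "synaptic", "dendritic", "axonal", "glial",
    "stromal", "luminal", "vascular", "neural",
]
_NOUNS = [
    "budding", "sprouting", "branching", "elongation", "compaction",
    "folding", "docking", "tethering", "priming", "remodeling", "scission",
    "fusion", "sorting", "trafficking", "anchoring", "bundling", "capping",
    "severing", "nucleation", "polymerization", "import", "export",
    "maturation", "clearance", "turnover", "assembly", "licensing",
    "silencing", "patterning", "guidance",
]

_ASPECT_QUALIFIER = {"P": "involved_in", "F": "enables", "C": "located_in"}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    The defaults describe the study conditions the rest of the package is
    exercised under: a 20-term DAG, 100 annotated genes, a 20-gene sample in
    which the planted term annotates 80% of sample genes but only 10% of the
    background — a strong, recoverable over-representation signal.
    """

    seed: int = 0
    n_terms: int = 20
    n_genes: int = 100
    dag_depth: int = 3
    planted_term_rate_sample: float = 0.8
    planted_term_rate_background: float = 0.1
    n_obsolete: int = 1
    synonym_rate: float = 0.3
    n_sample_genes: int = 20

    def __post_init__(self):
        if self.dag_depth < 2:
            raise FixtureSpecError("dag_depth must be >= 2")
        if not self.planted_term_rate_sample > self.planted_term_rate_background:
            raise FixtureSpecError(
                "planted_term_rate_sample must exceed planted_term_rate_background"
            )
        if self.n_sample_genes < 1 or self.n_sample_genes > self.n_genes:
            raise FixtureSpecError("need 1 <= n_sample_genes <= n_genes")
        live = self.n_terms - self.n_obsolete
        if live < self.dag_depth:
            raise FixtureSpecError("not enough live terms for the requested depth")
        if self.planted_term_rate_sample * self.n_sample_genes < 1:
            raise FixtureSpecError("planted sample rate infeasible (rate x count < 1)")
        n_bg = self.n_genes - self.n_sample_genes
        if n_bg > 0 and self.planted_term_rate_background * n_bg < 1:
            raise FixtureSpecError("planted background rate infeasible (rate x count < 1)")


def _make_labels(rng: random.Random, count: int) -> List[str]:
    combos = [(a, n) for a in _ADJECTIVES for n in _NOUNS]
    rng.shuffle(combos)
    labels: List[str] = []
    for a, n in combos:
        candidate = f"{a} {n}"
        # substring-free set: the mock model matches labels by substring
        if any(candidate in l or l in candidate for l in labels):
            continue
        labels.append(candidate)
        if len(labels) == count:
            return labels
    raise FixtureSpecError(f"cannot generate {count} distinct labels")


def make_fixture(spec: FixtureSpec) -> Tuple[Ontology, GeneAnnotationStore, GeneSet]:
    """Generate (ontology, annotation store, gene set) from a seeded spec."""
    rng = random.Random(spec.seed)
    n_live = spec.n_terms - spec.n_obsolete
    labels = _make_labels(rng, spec.n_terms)

    ids = [f"TOY:{i:07d}" for i in range(spec.n_terms)]
    live_ids, obsolete_ids = ids[:n_live], ids[n_live:]

    # layered DAG over live terms: single root, 1-2 parents in earlier layers
    layers: List[List[str]] = [[live_ids[0]]]
    rest = live_ids[1:]
    per_layer = max(1, len(rest) // (spec.dag_depth - 1))
    for d in range(1, spec.dag_depth):
        chunk = rest[(d - 1) * per_layer : d * per_layer] if d < spec.dag_depth - 1 else rest[(d - 1) * per_layer :]
        if chunk:
            layers.append(chunk)

    terms: Dict[str, OntologyTerm] = {}
    for depth, layer in enumerate(layers):
        for tid in layer:
            parents = set()
            if depth > 0:
                upstream = layers[depth - 1]
                for parent in rng.sample(upstream, k=min(len(upstream), rng.choice((1, 1, 2)))):
                    relation = "is_a" if rng.random() < 0.8 else "part_of"
                    parents.add((relation, parent))
            label = labels[ids.index(tid)]
            synonyms = set()
            if rng.random() < spec.synonym_rate:
                synonyms.add(f"{label} alias")
            terms[tid] = OntologyTerm(
                id=tid, label=label, synonyms=frozenset(synonyms),
                parents=frozenset(parents),
            )
    for i, tid in enumerate(obsolete_ids):
        label = labels[ids.index(tid)]
        # the first obsolete term carries a live synonym: a groundable probe
        synonyms = frozenset({f"retired {label}"} if i == 0 else set())
        terms[tid] = OntologyTerm(
            id=tid, label=label, synonyms=synonyms, obsolete=True,
            replaced_by=live_ids[0],
        )
    ontology = Ontology(terms)

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    sample = genes[: spec.n_sample_genes]
    background_rest = genes[spec.n_sample_genes :]

    planted = rng.choice(layers[-1])
    n_planted_sample = round(spec.planted_term_rate_sample * len(sample))
    n_planted_bg = round(spec.planted_term_rate_background * len(background_rest))

    direct: Dict[str, set] = {g: set() for g in genes}
    for g in rng.sample(sample, n_planted_sample):
        direct[g].add(planted)
    if background_rest and n_planted_bg:
        for g in rng.sample(background_rest, n_planted_bg):
            direct[g].add(planted)
    other_terms = [t for t in live_ids if t != planted]
    for g in genes:
        for t in rng.sample(other_terms, k=min(len(other_terms), rng.randint(1, 3))):
            direct[g].add(t)

    term_aspect = {t: (rng.choice("PPPFC")) for t in live_ids}
    store = GeneAnnotationStore(direct, genes, ontology, term_aspect)
    store.planted_term = planted  # fixture metadata; not part of store equality
    gene_set = GeneSet(name=f"planted-{spec.seed}", taxon="synthetic construct", genes=list(sample))
    return ontology, store, gene_set


def planted_term(spec: FixtureSpec) -> str:
    """Identifier of the planted over-represented term for a given spec."""
    _, store, _ = make_fixture(spec)
    return store.planted_term


def make_narrative_table(
    store: GeneAnnotationStore, seed: int = 0, distractor_rate: float = 0.5
) -> Dict[str, str]:
    """Narrative prose per gene, embedding its direct annotation labels.

    Texts read like terse curator summaries; distractor clauses are appended
    at ``distractor_rate`` so the texts are not pure label lists.
    """
    rng = random.Random(seed)
    table: Dict[str, str] = {}
    for gene in sorted(store.background):
        labels = sorted(
            store.ontology.terms[t].label for t in store.direct.get(gene, ())
        )
        if labels:
            text = "This gene participates in " + ", ".join(labels) + "."
        else:
            text = "This gene has no characterized function."
        if rng.random() < distractor_rate:
            text += f" Expression is broad across {rng.choice(_ADJECTIVES)} tissues."
        table[gene] = text
    return table


# -- serialization ---------------------------------------------------------


def write_obo(ontology: Ontology, path) -> None:
    """Write an OBO 1.4 flat file that round-trips through load_ontology."""
    lines = ["format-version: 1.4", "ontology: genesum-fixture", ""]
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.label:
            lines.append(f"name: {term.label}")
        for syn in sorted(term.synonyms):
            lines.append(f'synonym: "{syn}" EXACT []')
        for rel, parent in sorted(term.parents):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        if term.replaced_by:
            lines.append(f"replaced_by: {term.replaced_by}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gaf(store: GeneAnnotationStore, path, taxon_id: str = "taxon:32630") -> None:
    """Write annotations as GAF 2.2 (17 tab-separated columns)."""
    rows = []
    for gene in sorted(store.direct):
        for term in sorted(store.direct[gene]):
            aspect = store.term_aspect.get(term, "P")
            qualifier = _ASPECT_QUALIFIER.get(aspect, "involved_in")
            rows.append(
                "\t".join(
                    [
                        "GENESUM", gene, gene, qualifier, term, "GENESUM:fixture",
                        "IEA", "", aspect, "", "", "protein", taxon_id,
                        "20240101", "GENESUM", "", "",
                    ]
                )
            )
    Path(path).write_text("!gaf-version: 2.2\n" + "\n".join(rows) + "\n")


def write_fixture(
    ontology: Ontology,
    store: GeneAnnotationStore,
    gene_set: GeneSet,
    out_dir,
    narrative: Optional[Dict[str, str]] = None,
) -> Dict[str, str]:
    """Serialize a fixture to a directory; returns the file manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "ontology": str(out_dir / "ontology.obo"),
        "gaf": str(out_dir / "annotations.gaf"),
        "gene_set": str(out_dir / "gene_set.yaml"),
    }
    write_obo(ontology, manifest["ontology"])
    write_gaf(store, manifest["gaf"])
    write_gene_set(gene_set, manifest["gene_set"])
    if narrative is not None:
        manifest["narrative"] = str(out_dir / "narrative.tsv")
        write_narrative_table(narrative, manifest["narrative"])
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_fixture(manifest: Dict[str, str]):
    """Reload a serialized fixture; inverse of :func:`write_fixture`."""
    ontology = load_ontology(manifest["ontology"])
    store = load_gaf(manifest["gaf"], ontology)
    gene_set = load_gene_set(manifest["gene_set"])
    narrative = (
        load_narrative_table(manifest["narrative"]) if "narrative" in manifest else None
    )
    return ontology, store, gene_set, narrative
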