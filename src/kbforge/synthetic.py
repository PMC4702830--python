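"""Seeded synthetic corpora with known ground truth.

Documents are bags of filler pseudo-words with dictionary terms embedded, so
every stage of the pipeline — matching, enrichment, association scoring,
hypothesis generation — can be tested against structure planted by
construction:

* **enrichments**: each concept has one Bernoulli document-probability inside
  the topic subset (``p_kb``) and another outside (``p_background``); a
  concept is truly enriched iff its expected within-KB frequency exceeds the
  background one;
* **pairwise dependencies**: a planted pair co-occurs inside the KB with
  joint probability ``excess * p_a * p_b`` (capped at ``min(p_a, p_b)``,
  i.e. perfect nesting, when the requested excess is infeasible for the
  marginals); outside the KB members are independent;
* **ABC chains**: the two endpoints are drawn mutually exclusively (never in
  the same document, anywhere in the corpus) while the bridge concept is
  boosted in any document carrying an endpoint — yielding significant A–B
  and B–C associations with zero direct A–C co-occurrence.

KB membership is deterministic by document-id prefix (``KB...`` vs ``BG...``),
so KB counts are exactly controllable. Filler words and concept terms are
drawn from disjoint pseudo-word pools, isolating matcher correctness from the
statistics. A fixed seed makes generation byte-identical.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .corpus import Document, write_corpus
from .dictionaries import Concept, Dictionary
from .errors import IntegrityError, KbforgeError

DEFAULT_CATEGORY = {
    "Taxa": "taxonomy",
    "Genes": "genes",
    "Chemicals": "chemicals",
}


class ValidationError(KbforgeError):
    """A simulation spec that cannot be generated as stated."""


@dataclass(frozen=True)
class ConceptSpec:
    concept_id: str
    dictionary: str
    p_background: float  # per-document probability outside the topic subset
    p_kb: float          # per-document probability inside the topic subset
    terms: tuple[str, ...] = ()  # auto-generated pseudo-words when empty


@dataclass(frozen=True)
class PlantedPair:
    a: str
    b: str
    excess: float  # multiplier on the independent joint probability, within KB


@dataclass(frozen=True)
class PlantedChain:
    a: str
    b: str
    c: str


@dataclass
class SimulationSpec:
    n_docs: int = 500
    kb_fraction: float = 0.2
    concepts: list[ConceptSpec] = field(default_factory=list)
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_chains: list[PlantedChain] = field(default_factory=list)
    filler_vocab: int = 200
    doc_words: int = 40
    chain_bridge_prob: float = 0.8  # P(bridge | an endpoint is present), in KB
    seed: int = 0

    @property
    def n_kb_docs(self) -> int:
        return math.ceil(self.kb_fraction * self.n_docs)

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ValidationError("n_docs must be >= 1")
        if not (0 < self.kb_fraction <= 1):
            raise ValidationError("kb_fraction must lie in (0, 1]")
        if not self.concepts:
            raise ValidationError("at least one concept is required")
        ids = [c.concept_id for c in self.concepts]
        if len(set(ids)) != len(ids):
            raise ValidationError("concept_ids must be unique")
        for c in self.concepts:
            for p in (c.p_background, c.p_kb):
                if not (0 < p < 1):
                    raise ValidationError(
                        f"{c.concept_id}: probabilities must lie in (0, 1)")
        known = set(ids)
        committed: set[str] = set()

        def claim(cid: str, what: str) -> None:
            if cid not in known:
                raise ValidationError(f"{what} references unknown concept {cid!r}")
            if cid in committed:
                raise ValidationError(
                    f"concept {cid!r} appears in more than one planted structure")
            committed.add(cid)

        for p in self.planted_pairs:
            if p.excess < 1:
                raise ValidationError("pair excess must be >= 1")
            claim(p.a, "planted pair")
            claim(p.b, "planted pair")
        by_id = {c.concept_id: c for c in self.concepts}
        for ch in self.planted_chains:
            claim(ch.a, "planted chain")
            claim(ch.b, "planted chain")
            claim(ch.c, "planted chain")
            for attr in ("p_kb", "p_background"):
                pa = getattr(by_id[ch.a], attr)
                pc = getattr(by_id[ch.c], attr)
                if pa + pc > 1:
                    raise ValidationError(
                        f"chain ({ch.a},{ch.b},{ch.c}): endpoint probabilities "
                        f"{attr} sum to {pa + pc:.3f} > 1; mutually exclusive "
                        "draws are impossible")
        if not (0 < self.chain_bridge_prob < 1):
            raise ValidationError("chain_bridge_prob must lie in (0, 1)")


@dataclass
class GroundTruth:
    enriched_concepts: set[str]
    dependent_pairs: set[tuple[str, str]]  # sorted concept-id pairs
    expected_hypotheses: set[tuple[str, str]]
    all_concepts: set[str]

    def to_json(self) -> dict:
        return {
            "enriched_concepts": sorted(self.enriched_concepts),
            "dependent_pairs": sorted(list(p) for p in self.dependent_pairs),
            "expected_hypotheses": sorted(list(p) for p in self.expected_hypotheses),
            "all_concepts": sorted(self.all_concepts),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(
            enriched_concepts=set(obj["enriched_concepts"]),
            dependent_pairs={tuple(p) for p in obj["dependent_pairs"]},
            expected_hypotheses={tuple(p) for p in obj["expected_hypotheses"]},
            all_concepts=set(obj["all_concepts"]),
        )


@dataclass
class SyntheticDataset:
    corpus: list[Document]
    dictionaries: list[Dictionary]
    topic_ids: list[str]
    truth: GroundTruth
    spec: SimulationSpec


# --- pseudo-word machinery --------------------------------------------------

_SYLLABLES = ("ba", "be", "bi", "bo", "bu", "da", "de", "do", "du", "fa",
              "fe", "fi", "fo", "ga", "ge", "gi", "go", "gu", "ka", "ke",
              "ki", "ko", "ku", "la", "le", "li", "lo", "lu", "ma", "me",
              "mi", "mo", "mu", "na", "ne", "ni", "no", "nu", "pa", "pe",
              "pi", "po", "pu", "ra", "re", "ri", "ro", "ru", "sa", "se",
              "si", "so", "su", "ta", "te", "ti", "to", "tu", "va", "ve",
              "vi", "vo", "za", "ze", "zi", "zo", "zu")


def _pseudo_words(rng: np.random.Generator, count: int, n_syllables: int = 3
                  ) -> list[str]:
    """``count`` distinct pronounceable pseudo-words."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < count:
        idx = rng.integers(0, len(_SYLLABLES), size=n_syllables)
        word = "".join(_SYLLABLES[i] for i in idx)
        if word not in seen:
            seen.add(word)
            out.append(word)
    return out


def _assign_terms(spec: SimulationSpec, rng: np.random.Generator
                  ) -> tuple[list[str], dict[str, tuple[str, ...]]]:
    """Filler vocabulary and per-concept terms, mutually disjoint."""
    need_terms = [c for c in spec.concepts if not c.terms]
    words = _pseudo_words(rng, spec.filler_vocab + 2 * len(need_terms))
    filler = words[:spec.filler_vocab]
    pool = words[spec.filler_vocab:]
    terms: dict[str, tuple[str, ...]] = {}
    for i, c in enumerate(spec.concepts):
        if c.terms:
            terms[c.concept_id] = c.terms
    for i, c in enumerate(need_terms):
        root, variant = pool[2 * i], pool[2 * i + 1]
        terms[c.concept_id] = (root, f"{root} {variant}")
    return filler, terms


def _build_dictionaries(spec: SimulationSpec, terms: dict[str, tuple[str, ...]]
                        ) -> list[Dictionary]:
    dicts: dict[str, Dictionary] = {}
    for c in spec.concepts:
        d = dicts.get(c.dictionary)
        if d is None:
            d = Dictionary(name=c.dictionary,
                           category=DEFAULT_CATEGORY.get(c.dictionary, "general"))
            dicts[c.dictionary] = d
        tset = set(terms[c.concept_id])
        d.concepts[c.concept_id] = Concept(
            concept_id=c.concept_id, preferred_name=sorted(tset, key=len)[0],
            dictionary=c.dictionary, category=d.category,
            source_ids=[f"SRC:{c.concept_id}"], terms=tset)
    return [dicts[name] for name in sorted(dicts)]


# --- ground truth -----------------------------------------------------------

def _kb_marginal(spec: SimulationSpec, by_id: dict[str, ConceptSpec],
                 cid: str) -> float:
    """Expected within-KB document probability, accounting for chain boosts."""
    for ch in spec.planted_chains:
        if cid == ch.b:
            pa, pc = by_id[ch.a].p_kb, by_id[ch.c].p_kb
            p_end = pa + pc
            return spec.chain_bridge_prob * p_end + by_id[cid].p_kb * (1 - p_end)
    return by_id[cid].p_kb


def _ground_truth(spec: SimulationSpec) -> GroundTruth:
    by_id = {c.concept_id: c for c in spec.concepts}
    enriched = set()
    for c in spec.concepts:
        if _kb_marginal(spec, by_id, c.concept_id) > c.p_background + 1e-12:
            enriched.add(c.concept_id)
    dependent = set()
    for p in spec.planted_pairs:
        if p.excess > 1:
            dependent.add(tuple(sorted((p.a, p.b))))
    hyps = set()
    for ch in spec.planted_chains:
        dependent.add(tuple(sorted((ch.a, ch.b))))
        dependent.add(tuple(sorted((ch.b, ch.c))))
        hyps.add(tuple(sorted((ch.a, ch.c))))
    return GroundTruth(enriched_concepts=enriched, dependent_pairs=dependent,
                       expected_hypotheses=hyps,
                       all_concepts={c.concept_id for c in spec.concepts})


# --- generation -------------------------------------------------------------

def _presence_matrix(spec: SimulationSpec, rng: np.random.Generator
                     ) -> np.ndarray:
    """Boolean (n_docs, n_concepts) presence draws implementing the planted
    structure. Documents 0..n_kb-1 are the KB."""
    by_id = {c.concept_id: c for c in spec.concepts}
    col = {c.concept_id: i for i, c in enumerate(spec.concepts)}
    n, n_kb = spec.n_docs, spec.n_kb_docs
    in_kb = np.arange(n) < n_kb

    structured = {cid for p in spec.planted_pairs for cid in (p.a, p.b)}
    structured |= {cid for ch in spec.planted_chains for cid in (ch.a, ch.b, ch.c)}

    present = np.zeros((n, len(spec.concepts)), dtype=bool)
    # independent concepts, vectorized
    u = rng.random((n, len(spec.concepts)))
    for c in spec.concepts:
        if c.concept_id in structured:
            continue
        j = col[c.concept_id]
        thresh = np.where(in_kb, c.p_kb, c.p_background)
        present[:, j] = u[:, j] < thresh

    for p in spec.planted_pairs:
        ja, jb = col[p.a], col[p.b]
        pa_kb, pb_kb = by_id[p.a].p_kb, by_id[p.b].p_kb
        p11 = min(p.excess * pa_kb * pb_kb, min(pa_kb, pb_kb))
        v = rng.random(n)
        # KB documents: 2x2 joint with planted excess
        both = v < p11
        a_only = (v >= p11) & (v < pa_kb)  # p10 = pa - p11
        b_only = (v >= pa_kb) & (v < pa_kb + pb_kb - p11)  # p01 = pb - p11
        w = rng.random((n, 2))
        pa_bg, pb_bg = by_id[p.a].p_background, by_id[p.b].p_background
        present[:, ja] = np.where(in_kb, both | a_only, w[:, 0] < pa_bg)
        present[:, jb] = np.where(in_kb, both | b_only, w[:, 1] < pb_bg)

    for ch in spec.planted_chains:
        ja, jb, jc = col[ch.a], col[ch.b], col[ch.c]
        v = rng.random(n)
        w = rng.random(n)
        pa = np.where(in_kb, by_id[ch.a].p_kb, by_id[ch.a].p_background)
        pc = np.where(in_kb, by_id[ch.c].p_kb, by_id[ch.c].p_background)
        state_a = v < pa
        state_c = (v >= pa) & (v < pa + pc)  # mutually exclusive with a
        endpoint = state_a | state_c
        pb_base = np.where(in_kb, by_id[ch.b].p_kb, by_id[ch.b].p_background)
        pb = np.where(in_kb & endpoint, spec.chain_bridge_prob, pb_base)
        present[:, ja] = state_a
        present[:, jc] = state_c
        present[:, jb] = w < pb
    return present


def generate(spec: SimulationSpec, out_dir=None) -> SyntheticDataset:
    """Generate a corpus, dictionaries, topic id list and ground truth.

    With ``out_dir`` the dataset is also written to disk (``corpus.tsv``,
    ``dict_<name>.tsv``, ``topic_ids.txt``, ``truth.json``); identical specs
    (including the seed) produce byte-identical files.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    filler, terms = _assign_terms(spec, rng)
    dictionaries = _build_dictionaries(spec, terms)
    truth = _ground_truth(spec)

    present = _presence_matrix(spec, rng)
    filler_arr = np.array(filler)
    n_kb = spec.n_kb_docs
    docs: list[Document] = []
    concept_ids = [c.concept_id for c in spec.concepts]
    for i in range(spec.n_docs):
        doc_id = (f"KB{i:06d}" if i < n_kb else f"BG{i:06d}")
        title_words = filler_arr[rng.integers(0, len(filler_arr), size=3)]
        body = list(filler_arr[rng.integers(0, len(filler_arr), size=spec.doc_words)])
        for j, cid in enumerate(concept_ids):
            if present[i, j]:
                options = terms[cid]
                term = options[rng.integers(0, len(options))]
                body.insert(int(rng.integers(0, len(body) + 1)), term)
        docs.append(Document(doc_id=doc_id, title=" ".join(title_words),
                             abstract=" ".join(body)))
    topic_ids = [d.doc_id for d in docs[:n_kb]]

    dataset = SyntheticDataset(corpus=docs, dictionaries=dictionaries,
                               topic_ids=topic_ids, truth=truth, spec=spec)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    write_corpus(dataset.corpus, os.path.join(out_dir, "corpus.tsv"))
    for d in dataset.dictionaries:
        path = os.path.join(out_dir, f"dict_{d.name}.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("concept_id\tdictionary_name\tdictionary_category\t"
                     "preferred_name\tterm\tsource_id\n")
            for cid in sorted(d.concepts):
                c = d.concepts[cid]
                src = c.source_ids[0] if c.source_ids else ""
                for term in sorted(c.terms):
                    fh.write(f"{cid}\t{d.name}\t{d.category}\t"
                             f"{c.preferred_name}\t{term}\t{src}\n")
    with open(os.path.join(out_dir, "topic_ids.txt"), "w", encoding="utf-8") as fh:
        for doc_id in dataset.topic_ids:
            fh.write(doc_id + "\n")
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(dataset.truth.to_json(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_json(json.load(fh))


# --- spec files -------------------------------------------------------------

def spec_from_dict(obj: dict) -> SimulationSpec:
    concepts = [ConceptSpec(concept_id=c["concept_id"],
                            dictionary=c.get("dictionary", "Concepts"),
                            p_background=float(c["p_background"]),
                            p_kb=float(c["p_kb"]),
                            terms=tuple(c.get("terms", ())))
                for c in obj.get("concepts", [])]
    pairs = [PlantedPair(a=p["a"], b=p["b"], excess=float(p.get("excess", 1.0)))
             for p in obj.get("planted_pairs", [])]
    chains = [PlantedChain(a=c["a"], b=c["b"], c=c["c"])
              for c in obj.get("planted_chains", [])]
    return SimulationSpec(
        n_docs=int(obj.get("n_docs", 500)),
        kb_fraction=float(obj.get("kb_fraction", 0.2)),
        concepts=concepts, planted_pairs=pairs, planted_chains=chains,
        filler_vocab=int(obj.get("filler_vocab", 200)),
        doc_words=int(obj.get("doc_words", 40)),
        chain_bridge_prob=float(obj.get("chain_bridge_prob", 0.8)),
        seed=int(obj.get("seed", 0)))


def spec_from_yaml(path) -> SimulationSpec:
    import yaml
    with open(path, encoding="utf-8") as fh:
        return spec_from_dict(yaml.safe_load(fh))


# --- canned study designs ---------------------------------------------------

def null_spec(seed: int, n_docs: int = 500, kb_fraction: float = 0.2,
              n_concepts: int = 20) -> SimulationSpec:
    """No planted structure: every concept equally likely inside and outside
    the topic subset, so any reported enrichment or association is false."""
    concepts = []
    for i in range(n_concepts):
        p = 0.05 + 0.25 * (i / max(1, n_concepts - 1))
        dictionary = ("Taxa", "Genes", "Chemicals")[i % 3]
        concepts.append(ConceptSpec(concept_id=f"C{i:03d}", dictionary=dictionary,
                                    p_background=p, p_kb=p))
    return SimulationSpec(n_docs=n_docs, kb_fraction=kb_fraction,
                          concepts=concepts, seed=seed)


def pair_power_spec(seed: int, excess: float = 4.0, marginal: float = 0.3,
                    kb_docs: int = 200, n_docs: int = 600,
                    n_null_concepts: int = 10) -> SimulationSpec:
    """One planted dependent pair (within-KB marginals ``marginal``, joint
    excess ``excess``) among null concepts; the pair members are enriched in
    the KB (background probability 0.05) so they enter the association
    stage."""
    concepts = [
        ConceptSpec("PAIR_A", "Genes", p_background=0.05, p_kb=marginal),
        ConceptSpec("PAIR_B", "Chemicals", p_background=0.05, p_kb=marginal),
    ]
    for i in range(n_null_concepts):
        p = 0.05 + 0.15 * (i / max(1, n_null_concepts - 1))
        concepts.append(ConceptSpec(f"N{i:03d}", "Taxa", p_background=p, p_kb=p))
    return SimulationSpec(
        n_docs=n_docs, kb_fraction=kb_docs / n_docs, concepts=concepts,
        planted_pairs=[PlantedPair("PAIR_A", "PAIR_B", excess=excess)],
        seed=seed)


def chain_power_spec(seed: int, kb_docs: int = 200, n_docs: int = 600,
                     n_null_concepts: int = 10) -> SimulationSpec:
    """One planted A–B–C chain (zero direct A–C co-occurrence) among null
    concepts; endpoints and bridge are enriched in the KB."""
    concepts = [
        ConceptSpec("CH_A", "Chemicals", p_background=0.04, p_kb=0.3),
        ConceptSpec("CH_B", "Genes", p_background=0.02, p_kb=0.1),
        ConceptSpec("CH_C", "Taxa", p_background=0.04, p_kb=0.3),
    ]
    for i in range(n_null_concepts):
        p = 0.05 + 0.15 * (i / max(1, n_null_concepts - 1))
        concepts.append(ConceptSpec(f"N{i:03d}", "Taxa", p_background=p, p_kb=p))
    return SimulationSpec(
        n_docs=n_docs, kb_fraction=kb_docs / n_docs, concepts=concepts,
        planted_chains=[PlantedChain("CH_A", "CH_B", "CH_C")],
        seed=seed)


# --- recovery evaluation ----------------------------------------------------

@dataclass(frozen=True)
class StageRecovery:
    stage: str
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float | None  # None when nothing was predicted
    recall: float


def _score_sets(stage: str, predicted: set, truth_set: set) -> StageRecovery:
    tp = len(predicted & truth_set)
    fp = len(predicted - truth_set)
    fn = len(truth_set - predicted)
    precision = tp / (tp + fp) if predicted else None
    recall = tp / (tp + fn) if truth_set else 1.0
    return StageRecovery(stage, tp, fp, fn, precision, recall)


def evaluate_recovery(enriched, associations, hypotheses,
                      truth: GroundTruth) -> list[StageRecovery]:
    """Precision/recall of each pipeline stage against the planted truth.

    ``enriched``, ``associations`` and ``hypotheses`` are the outputs of
    :func:`kbforge.stats.enrich_concepts`, :func:`kbforge.stats.score_associations`
    and :func:`kbforge.hypotheses.generate_hypotheses`. Comparison is at the
    concept-id level; ids unknown to the truth are an integrity error.
    """
    pred_concepts = {e.concept_id for e in enriched}
    pred_pairs = {tuple(sorted((x.concept_a.concept_id, x.concept_b.concept_id)))
                  for x in associations}
    pred_hyps = {tuple(sorted((h.concept_a.concept_id, h.concept_c.concept_id)))
                 for h in hypotheses}
    stray = (pred_concepts | {c for p in pred_pairs for c in p}
             | {c for p in pred_hyps for c in p}) - truth.all_concepts
    if stray:
        raise IntegrityError(
            f"results mention concept ids unknown to the ground truth: "
            f"{', '.join(sorted(stray))}")
    return [
        _score_sets("enrichment", pred_concepts, truth.enriched_concepts),
        _score_sets("associations", pred_pairs, truth.dependent_pairs),
        _score_sets("hypotheses", pred_hyps, truth.expected_hypotheses),
    ]


def write_recovery_tsv(rows: list[StageRecovery], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stage\ttrue_positives\tfalse_positives\tfalse_negatives\t"
                 "precision\trecall\n")
        for r in rows:
            prec = "NA" if r.precision is None else f"{r.precision:.6g}"
            fh.write(f"{r.stage}\t{r.true_positives}\t{r.false_positives}\t"
                     f"{r.false_negatives}\t{prec}\t{r.recall:.6g}\n")
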