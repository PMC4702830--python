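"""One-call pipeline: corpus + dictionaries + topic list -> KB tables.

Convenience layer gluing the stages together in the canonical order:
ambiguity-clean the dictionaries, build the global index, restrict it to the
topic subset, compute enriched concepts, score their pairwise associations
and generate transitive hypotheses. Each stage remains individually callable
from its own module; this facade exists for scripts, tests and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dictionaries import Dictionary, exclude_ambiguous_terms
from .hypotheses import Hypothesis, RoleFilter, generate_hypotheses
from .index import GlobalIndex, KnowledgeBase, build_global_index, create_kb
from .stats import Association, EnrichedConcept, enrich_concepts, score_associations


@dataclass
class PipelineResult:
    index: GlobalIndex
    kb: KnowledgeBase
    enriched: list[EnrichedConcept]
    associations: list[Association]
    hypotheses: list[Hypothesis]


def run_pipeline(corpus, dictionaries: list[Dictionary], topic_ids,
                 kb_name: str = "kb", alpha: float = 0.05,
                 background: str = "corpus", clean: bool = True,
                 hypothesis_constraints: RoleFilter | None = None,
                 with_hypotheses: bool = True) -> PipelineResult:
    if clean:
        dictionaries = [exclude_ambiguous_terms(d) for d in dictionaries]
    index = build_global_index(corpus, dictionaries)
    kb = create_kb(index, topic_ids, kb_name)
    enriched = enrich_concepts(kb, index, dictionaries, alpha=alpha)
    associations = score_associations(kb, enriched, index, alpha=alpha,
                                      background=background)
    hypotheses = []
    if with_hypotheses:
        hypotheses = generate_hypotheses(associations, kb,
                                         constraints=hypothesis_constraints)
    return PipelineResult(index=index, kb=kb, enriched=enriched,
                          associations=associations, hypotheses=hypotheses)
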