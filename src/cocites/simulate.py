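"""Synthetic citation corpora with planted eligible studies.

The generator emulates the situation the search method targets: a topic
with a set of *eligible* studies (the gold standard a reviewer wants to
re-find), a much larger pool of topically unrelated *noise* works, and a
population of citing articles whose reference lists preferentially
contain the eligible works.  Each citing article includes each citable
eligible work independently with probability ``p_cite_eligible`` and each
noise work with probability ``p_cite_noise`` — per-work Bernoulli
sampling, so a work's co-citation count across ``n`` citing articles is
exactly Binomial(n, p), which gives the test suite an analytic
distributional oracle.  With the default parameters most co-cited noise
works are co-cited exactly once, reproducing the heavy-tailed, roughly
80 %-singletons shape observed on real corpora.

Three strata of hard-to-find eligible studies are planted:

* a *recent-uncited* fraction — published in the search year, cited by
  nobody, but citing two or more older eligible studies (findable only
  through the direct-citation stage),
* a *disconnected* fraction — no direct citation links to or from any
  other eligible study (findable only through co-citation), and
* metadata strata (abstract-only, non-English, pre-1975) for exercising
  missed-study classification.

Reproducibility: one seed governs the whole corpus, and every article
draws from its own counter-based substream, so enlarging the corpus never
perturbs the articles already generated.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import CoCitationTable, SeedSet, run_cocitation_search
from .io import ArticleRecord, CitationCorpus, RefKey
from .selection import select_min_count

DEFAULT_STRATA = {"abstract": 0.05, "non_english": 0.05, "pre1975": 0.05}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic corpus.

    Defaults describe a moderately cited topic: 15 eligible studies, a
    3,000-work unrelated reference pool and 200 citing articles, with
    citation probabilities 0.3 (eligible) versus 0.003 (noise) chosen so
    that, among co-cited candidates, roughly four in five are co-cited
    exactly once.  ``refs_per_citing`` optionally adds per-article
    incidental references (mean, dispersion of a negative binomial),
    unique to their citing article, thickening the singleton tail.
    """

    n_eligible: int = 15
    n_noise: int = 3000
    n_citing: int = 200
    p_cite_eligible: float = 0.3
    p_cite_noise: float = 0.003
    refs_per_citing: Optional[tuple[float, float]] = None
    frac_disconnected_eligible: float = 0.2
    frac_recent_uncited: float = 0.1
    strata_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STRATA))
    search_year: int = 2015
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("p_cite_eligible", "p_cite_noise", "frac_disconnected_eligible", "frac_recent_uncited"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name, value in self.strata_probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"strata_probs[{name!r}] must be in [0, 1], got {value}")
        if self.n_citing < 1:
            raise ValueError("n_citing must be >= 1")
        if self.n_eligible < 1:
            raise ValueError("n_eligible must be >= 1")
        n_recent = int(round(self.frac_recent_uncited * self.n_eligible))
        n_disc = int(round(self.frac_disconnected_eligible * self.n_eligible))
        if self.n_eligible - n_recent - n_disc < 1:
            raise ValueError(
                "infeasible config: recent-uncited and disconnected fractions leave no citable, "
                "connected eligible study to seed the search"
            )


@dataclass
class SimulatedCorpus:
    """A generated corpus with all planted labels."""

    corpus: CitationCorpus
    seeds: SeedSet
    gold_included: set[RefKey]
    eligible_keys: list[RefKey]
    recent_keys: set[RefKey]
    disconnected_keys: set[RefKey]
    noise_keys: list[RefKey]
    config: SimulationConfig


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def generate_corpus(config: SimulationConfig) -> SimulatedCorpus:
    """Generate one corpus; identical config (incl. seed) gives identical output."""
    n = config.n_eligible
    n_recent = int(round(config.frac_recent_uncited * n))
    n_disc = int(round(config.frac_disconnected_eligible * n))

    # Partition eligible indices: recent-uncited, disconnected, connected.
    recent_idx = set(range(n_recent))
    disc_idx = set(range(n_recent, n_recent + n_disc))
    connected_idx = [i for i in range(n) if i not in recent_idx and i not in disc_idx]

    eligible: list[ArticleRecord] = []
    for i in range(n):
        rng = _substream(config.rng_seed, 1, i)
        abstract = rng.random() < config.strata_probs.get("abstract", 0.0)
        non_english = rng.random() < config.strata_probs.get("non_english", 0.0)
        pre1975 = rng.random() < config.strata_probs.get("pre1975", 0.0)
        if i in recent_idx:
            year = config.search_year
        elif pre1975:
            year = int(rng.integers(1950, 1975))
        else:
            year = int(rng.integers(1985, 2011))
        eligible.append(
            ArticleRecord(
                article_id=f"E{i:03d}",
                title=f"Eligible study {i}",
                first_author_surname=f"AUTHOR{i:03d} A",
                year=year,
                source="J SYNTH EVID",
                doi=f"10.5555/elig.{i:03d}",
                language="German" if non_english else "English",
                doc_type="abstract" if abstract else "article",
            )
        )

    # Direct citation links among eligible studies.  Connected studies cite
    # earlier connected studies (chained so none is accidentally isolated);
    # recent-uncited studies cite >= 2 older eligible studies; disconnected
    # studies neither cite nor are cited by any eligible study.
    order = sorted(connected_idx, key=lambda i: (eligible[i].year, eligible[i].article_id))
    for pos, i in enumerate(order):
        rng = _substream(config.rng_seed, 4, i)
        earlier = order[:pos]
        targets = [j for j in earlier if rng.random() < 0.4]
        if earlier and not targets:
            targets = [earlier[-1]]
        eligible[i].cited_refs.extend(eligible[j].refkey for j in targets)
    for i in sorted(recent_idx):
        rng = _substream(config.rng_seed, 4, i)
        k = min(2, len(connected_idx))
        targets = sorted(rng.choice(len(connected_idx), size=k, replace=False)) if k else []
        eligible[i].cited_refs.extend(eligible[connected_idx[int(t)]].refkey for t in targets)

    eligible_keys = [a.refkey for a in eligible]
    citable = np.array([0.0 if i in recent_idx else config.p_cite_eligible for i in range(n)])
    noise_keys = [f"noise-{i:05d}|2000|j unrelated" for i in range(config.n_noise)]
    noise_arr = np.array(noise_keys, dtype=object)
    eligible_arr = np.array(eligible_keys, dtype=object)

    citing: list[ArticleRecord] = []
    for c in range(config.n_citing):
        rng = _substream(config.rng_seed, 2, c)
        elig_mask = rng.random(n) < citable
        noise_mask = rng.random(config.n_noise) < config.p_cite_noise
        refs = list(eligible_arr[elig_mask]) + list(noise_arr[noise_mask])
        if config.refs_per_citing is not None:
            mean, dispersion = config.refs_per_citing
            p = dispersion / (dispersion + mean)
            n_incidental = int(rng.negative_binomial(dispersion, p))
            refs.extend(f"incidental-{c:04d}-{j:03d}" for j in range(n_incidental))
        citing.append(
            ArticleRecord(
                article_id=f"C{c:04d}",
                title=f"Citing article {c}",
                first_author_surname=f"CITER{c:04d} B",
                year=int(rng.integers(2005, config.search_year)),
                source="J CITATIONS",
                doi=f"10.5555/cite.{c:04d}",
                language="English",
                doc_type="article",
                cited_refs=refs,
            )
        )

    corpus = CitationCorpus(eligible + citing)

    # Seeds: two cited, connected eligible studies (one if only one is cited).
    rng = _substream(config.rng_seed, 3)
    candidates = [i for i in connected_idx if corpus.cited_by.get(eligible[i].refkey)]
    if not candidates:
        raise ValueError("infeasible config: no connected eligible study was cited; cannot seed")
    k = min(2, len(candidates))
    chosen = rng.choice(len(candidates), size=k, replace=False)
    known_ids = {eligible[candidates[int(i)]].article_id for i in chosen}
    seeds = SeedSet(known_ids=known_ids, exclusion_ids=set(), date_cutoff_year=None)

    return SimulatedCorpus(
        corpus=corpus,
        seeds=seeds,
        gold_included=set(eligible_keys),
        eligible_keys=eligible_keys,
        recent_keys={eligible_keys[i] for i in recent_idx},
        disconnected_keys={eligible_keys[i] for i in disc_idx},
        noise_keys=noise_keys,
        config=config,
    )


@dataclass
class CorpusSummary:
    """Co-citation count distribution for one corpus and seed set."""

    histogram: dict[int, int]
    n_candidates: int
    fraction_once: float
    n_citing: int


def summarize_corpus(corpus: CitationCorpus, seeds: SeedSet) -> CorpusSummary:
    """Histogram of co-citation counts and the fraction of once-co-cited candidates."""
    table = run_cocitation_search(corpus, seeds)
    hist = Counter(r.cocitation_count for r in table.records)
    n_candidates = len(table.records)
    fraction_once = (hist.get(1, 0) / n_candidates) if n_candidates else 0.0
    return CorpusSummary(
        histogram=dict(sorted(hist.items())),
        n_candidates=n_candidates,
        fraction_once=fraction_once,
        n_citing=table.n_citing,
    )


def recovery_metrics(config: SimulationConfig) -> dict[str, float]:
    """Run the full pipeline on one simulated corpus and score it.

    Returns stage-1 recall of citable (non-recent) eligible studies under
    the minimum-count-2 threshold, the screening burden as a fraction of
    the candidate-work pool (eligible + noise), and the recent-uncited and
    disconnected retrieval bookkeeping for the two-stage protocol.
    """
    from .direct import run_two_stage_search

    sim = generate_corpus(config)
    table: CoCitationTable = run_cocitation_search(sim.corpus, sim.seeds)
    min2 = select_min_count(table, 2)
    selected = min2.key_set

    seed_keys = {sim.corpus.refkey_of_article[i] for i in sim.seeds.known_ids}
    citable_gold = (sim.gold_included - sim.recent_keys) - seed_keys
    recall = len(selected & citable_gold) / len(citable_gold) if citable_gold else 1.0
    universe = config.n_eligible + config.n_noise
    burden = min2.size / universe

    two_stage = run_two_stage_search(sim.corpus, sim.seeds)
    stage1_keys = two_stage.stage1_selection.key_set
    combined_keys = two_stage.combined.key_set
    disc = sim.disconnected_keys - seed_keys
    return {
        "recall_min2": recall,
        "screening_fraction": burden,
        "n_recent": len(sim.recent_keys),
        "recent_in_stage1": len(stage1_keys & sim.recent_keys),
        "recent_in_combined": len(combined_keys & sim.recent_keys),
        "n_disconnected": len(disc),
        "disconnected_in_stage1_min2": len(selected & disc),
        "disconnected_cocited": len({r.refkey for r in table.records} & disc),
    }
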