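"""Shared fixtures: a small terminology forest, a hand-built lexicon, and a
session-scoped synthetic study (corpus + ground truth + full pipeline run)."""

from __future__ import annotations

from datetime import datetime

import pytest

import tweetsurv as ts
from tweetsurv import synthetic_data as sd
from tweetsurv.lexicon import TerminologyNode


def make_tweet(tweet_id="t0", text="hello", lat=0.0, lon=0.0, lang="en"):
    return ts.Tweet(
        tweet_id=tweet_id,
        text=text,
        lat=lat,
        lon=lon,
        timestamp=datetime(2016, 11, 1, 12, 0, 0),
        lang=lang,
    )


@pytest.fixture
def mk_tweet():
    return make_tweet


@pytest.fixture
def purpura_forest():
    """Three-level idiopathic-disease hierarchy with synonyms on two leaves."""
    return {
        "n1": TerminologyNode("n1", "idiopathic disease", (), ("n2",)),
        "n2": TerminologyNode(
            "n2", "idiopathic thrombocytopenic purpura", ("itp",), ("n3",)
        ),
        "n3": TerminologyNode(
            "n3", "acute idiopathic thrombocytopenic purpura", (), ()
        ),
    }


@pytest.fixture
def small_lexicon():
    return ts.build_lexicon(
        [
            ("heart failure", ["cardiac failure"]),
            ("kidney stone", []),
            ("muscle atrophy", []),
            ("flu", ["influenza", "grippe"]),
            ("lassa fever", []),
        ]
    )


class SimStudy:
    """One fully generated and analysed synthetic study."""

    def __init__(self, seed=11, n_tweets=5000):
        self.seed = seed
        self.cfg = sd.SimConfig(seed=seed, n_tweets=n_tweets)
        self.airports, self.hospitals = sd.generate_pois(8, 12, seed=seed)
        self.tweets, self.truth = sd.generate_corpus(
            self.cfg, self.airports, self.hospitals
        )
        self.lexicon = ts.build_lexicon([(t, []) for t, _w in self.cfg.term_catalog])
        self.result = ts.run_pipeline(
            self.tweets, self.lexicon, self.airports, self.hospitals
        )
        self.metrics = sd.evaluate_pipeline(
            self.tweets,
            self.truth,
            self.result.mentions_by_tweet,
            self.result.memberships,
            self.result.filter_result,
        )


@pytest.fixture(scope="session")
def sim_study():
    return SimStudy()
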