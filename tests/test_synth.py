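"""Synthetic generator: determinism, confounding structure, corpus I/O."""

import numpy as np
import pytest
from scipy import stats

from medvigil.errors import GenerationError, ParseError, ValidationError
from medvigil.synth import (
    SimConfig,
    generate_population,
    read_corpus,
    write_corpus,
)


def _fast_cfg(**kw):
    base = dict(n_treatment=100, n_control=100, posts_per_user_mean=8.0, seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestGeneratePopulation:
    def test_population_size_and_arms(self, small_population):
        cfg, tls = small_population
        assert len(tls) == cfg.n_treatment + cfg.n_control
        treated = [t for t in tls if t.is_treatment]
        assert len(treated) == cfg.n_treatment
        for t in treated:
            assert t.drug in cfg.drugs
            assert cfg.window_start < t.disclosure_time < cfg.window_end
            assert any(p.text.startswith("i took ") for p in t.posts)

    def test_posts_sorted_and_min_count(self, small_population):
        cfg, tls = small_population
        for tl in tls:
            ts = [p.timestamp for p in tl.posts]
            assert ts == sorted(ts)
            assert len(tl.posts) >= cfg.min_posts

    def test_seed_determinism_is_exact(self):
        a = generate_population(_fast_cfg(seed=7))
        b = generate_population(_fast_cfg(seed=7))
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_population(_fast_cfg(seed=1))
        b = generate_population(_fast_cfg(seed=2))
        assert a != b

    def test_null_injection_and_planting_gives_no_planted_terms(self):
        cfg = _fast_cfg(
            inject_rate_improved=0.0,
            inject_rate_worsened=0.0,
        )
        tls = generate_population(cfg)
        planted_tokens = {
            tok
            for term in cfg.planted_terms_improved + cfg.planted_terms_worsened
            for tok in term.split()
        }
        for tl in tls:
            for p in tl.posts:
                assert planted_tokens.isdisjoint(p.text.split())

    def test_zero_gamma_decorrelates_treatment(self):
        # Monte-Carlo: with gamma = 0 the treated/control covariate
        # correlation vanishes (|r| < 0.05 at n=2,000 pooled over replicates)
        rs = []
        for rep in range(20):
            cfg = SimConfig(
                n_treatment=100,
                n_control=100,
                posts_per_user_mean=5.0,
                confounder_coefs=(0.0, 0.0, 0.0, 0.0),
                seed=100 + rep,
            )
            tls = generate_population(cfg)
            x = np.array([t.truth["log_followers"] for t in tls])
            y = np.array([float(t.is_treatment) for t in tls])
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(float(np.mean(rs))) < 0.05

    def test_confounding_is_real_with_nonzero_gamma(self):
        cfg = SimConfig(n_treatment=1000, n_control=1000, posts_per_user_mean=5.0, seed=3)
        tls = generate_population(cfg)
        x_t = np.array([t.truth["log_followers"] for t in tls if t.is_treatment])
        x_c = np.array([t.truth["log_followers"] for t in tls if not t.is_treatment])
        pooled = np.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2)
        smd = abs(x_t.mean() - x_c.mean()) / pooled
        assert smd > 0.1

    def test_delta_ordering_recoverable_from_symptom_fractions(self):
        # users' realized post-window symptom-post fraction anti-correlates
        # with their hidden improvement effect
        cfg = SimConfig(n_treatment=150, n_control=50, posts_per_user_mean=60.0, seed=5)
        tls = generate_population(cfg)
        marker = cfg.resolved_markers()["depression"]
        deltas, fracs = [], []
        for tl in tls:
            if not tl.is_treatment:
                continue
            post = [p for p in tl.posts if p.timestamp > tl.disclosure_time]
            if len(post) < 10:
                continue
            flagged = sum(1 for p in post if marker in p.text.split())
            deltas.append(tl.truth["delta"])
            fracs.append(flagged / len(post))
        rho = stats.spearmanr(deltas, fracs).statistic
        assert rho < -0.5

    def test_infeasible_quota_raises(self):
        from medvigil.synth import _select_treated

        rng = np.random.default_rng(0)
        with pytest.raises(GenerationError, match="quota"):
            _select_treated(rng, np.zeros(50), 10)

    def test_quota_is_exact_under_confounding(self):
        cfg = _fast_cfg(seed=9)
        tls = generate_population(cfg)
        assert sum(t.is_treatment for t in tls) == cfg.n_treatment

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(n_treatment=0).validate()
        with pytest.raises(ValidationError):
            SimConfig(inject_rate_improved=1.5).validate()
        with pytest.raises(ValidationError):
            SimConfig(window_start=10, window_end=5).validate()
        with pytest.raises(ValidationError):
            SimConfig(vocab_size=3).validate()


class TestCorpusIO:
    def test_round_trip_is_lossless(self, small_population, tmp_path):
        _, tls = small_population
        path = write_corpus(tls, tmp_path / "corpus.jsonl")
        assert read_corpus(path) == tls

    def test_truth_hidden_without_sidecar_access(self, small_population, tmp_path):
        _, tls = small_population
        path = write_corpus(tls, tmp_path / "corpus.jsonl")
        blind = read_corpus(path, with_truth=False)
        assert all(t.truth is None for t in blind)
        assert all(not t.is_treatment for t in blind)
        # observable metadata still present
        by_id = {t.user_id: t for t in tls}
        assert all(t.n_followers == by_id[t.user_id].n_followers for t in blind)

    def test_empty_corpus_round_trip(self, tmp_path):
        path = write_corpus([], tmp_path / "empty.jsonl")
        assert path.read_text() == ""
        assert read_corpus(path) == []

    def test_truth_sidecar_has_one_row_per_user(self, tmp_path):
        tls = generate_population(_fast_cfg(n_treatment=30, n_control=20))
        write_corpus(tls, tmp_path / "c.jsonl")
        lines = (tmp_path / "c.truth.tsv").read_text().strip().splitlines()
        assert len(lines) - 1 == 50

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.jsonl"
        p.write_text(
            '{"user_id":"u1","post_id":"p1","timestamp":5,"text":"ok"}\n'
            "{not json}\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_corpus(p)
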