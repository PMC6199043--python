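"""Seeded desk-scale benchmarks exercising every engine end-to-end.

These routines regenerate their corpora from scratch on each call; they
exist so the acceptance checks and the reporting script share one code
path.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import contact, propensity, rasa, seqio, synthetic, tmh


def tmh_recovery_benchmark(
    n_train: int = 300,
    n_test: int = 100,
    seed_train: int = 1,
    seed_test: int = 2,
    windows: tuple[int, ...] = (13, 15),
    max_refs: int = 20_000,
    loo_sample: int = 1_000,
) -> tmh.TmhEvalResult:
    """Train the helix engine on one seeded corpus, evaluate on another."""
    train = synthetic.generate_membrane_protein_corpus(
        synthetic.TopologyGeneratorConfig(n_proteins=n_train, seed=seed_train))
    test = synthetic.generate_membrane_protein_corpus(
        synthetic.TopologyGeneratorConfig(n_proteins=n_test, seed=seed_test))
    sets = propensity.build_training_set(train, windows=windows)
    models = {
        w: propensity.train_oetknn(X, y, window_size=w, max_refs=max_refs,
                                   loo_sample=loo_sample, seed=seed_train)
        for w, (X, y) in sets.items()
    }
    cfg = propensity.WindowConfig(sizes=windows)
    seg_cfg = tmh.SegmenterConfig()
    pairs = []
    for record, topo in test:
        profile = seqio.pseudo_profile(record)
        track = propensity.predict_propensity(profile, models, cfg)
        smooth = tmh.median_filter(track, seg_cfg.median_window)
        pairs.append((tmh.segment_track(smooth, seg_cfg), topo))
    return tmh.evaluate_topologies(pairs)


def planted_contact_benchmark(
    L: int = 50,
    depth: int = 400,
    n_pairs: int = 10,
    coupling: float = 0.9,
    seed: int = 3,
    train_seeds: tuple[int, ...] = (103, 104, 105),
    fuse_weight: float = 0.5,
) -> dict[str, float]:
    """Top-``n_pairs`` precision of each engine on a planted-pair MSA.

    The supervised ensemble is trained on independently seeded MSAs so
    the evaluation alignment is strictly held out.
    """

    def build(seed_):
        msa, planted = synthetic.generate_planted_contact_msa(
            L=L, depth=depth, n_pairs=n_pairs, coupling=coupling, seed=seed_)
        return msa, planted, seqio.profile_from_msa(msa)

    feats, labels = [], []
    for s in train_seeds:
        _, planted, prof = build(s)
        pl = set(planted)
        for a in range(1, L + 1):
            for b in range(a + contact.DEFAULT_MIN_SEPARATION, L + 1):
                feats.append(contact.pair_features(prof, a, b))
                labels.append(1 if (a - 1, b - 1) in pl else 0)
    ensemble = contact.train_contact_ensemble(
        np.asarray(feats), np.asarray(labels), n_models=10, seed=seed)

    msa, planted, prof = build(seed)
    truth = np.zeros((L, L), dtype=int)
    for i, j in planted:
        truth[i, j] = truth[j, i] = 1

    ml_map = contact.ml_contact_map(prof, ensemble)
    ml_map.truth = truth
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coevo_map = contact.coevolution_scores(msa)
    coevo_map.truth = truth
    fused = contact.fuse_contact_maps(coevo_map, ml_map, fuse_weight)

    k = n_pairs
    return {
        "coevolution_topk": contact.top_k_accuracy(coevo_map, k),
        "ml_topk": contact.top_k_accuracy(ml_map, k),
        "fused_topk": contact.top_k_accuracy(fused, k),
        "n_unmasked_pairs": int(np.triu(coevo_map.unmasked(), 1).sum()),
    }


def rasa_fusion_benchmark(
    n_proteins: int = 100,
    noise_sd: float = 10.0,
    train_fraction: float = 0.8,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    max_pool: int = 8_000,
    max_svr: int = 3_000,
) -> list[dict[str, float]]:
    """Per-seed held-out MAE / Pearson r of both engines and the fusion."""
    results = []
    for seed in seeds:
        corpus = synthetic.generate_membrane_protein_corpus(
            synthetic.TopologyGeneratorConfig(n_proteins=n_proteins, seed=seed))
        tracks = synthetic.generate_rasa_corpus(corpus, noise_sd=noise_sd,
                                                seed=seed + 1000)
        profiles = [seqio.pseudo_profile(r) for r, _ in corpus]
        n_train = int(round(train_fraction * n_proteins))
        pool = rasa.build_template_pool(
            list(zip(profiles[:n_train], tracks[:n_train])),
            max_entries=max_pool, seed=seed)
        feats = [rasa.rasa_features(rec, prof, topo)
                 for (rec, topo), prof in zip(corpus[:n_train], profiles[:n_train])]
        regressor = rasa.train_rasa_regressor(
            np.vstack(feats),
            np.concatenate([t.values for t in tracks[:n_train]]),
            max_samples=max_svr, seed=seed)
        fcfg = rasa.RasaFusionConfig()
        t_pairs, r_pairs, f_pairs = [], [], []
        for (rec, topo), prof, obs in zip(corpus[n_train:], profiles[n_train:],
                                          tracks[n_train:]):
            t_track, sim = rasa.template_predict(prof, pool, fcfg)
            F = rasa.rasa_features(rec, prof, topo)
            r_track = rasa.RasaTrack(record_id=rec.id,
                                     values=regressor.predict(F))
            fused, _ = rasa.fuse_rasa(t_track, sim, r_track, fcfg)
            t_pairs.append((t_track, obs))
            r_pairs.append((r_track, obs))
            f_pairs.append((fused, obs))
        r_t, mae_t = rasa.evaluate_rasa_pooled(t_pairs)
        r_r, mae_r = rasa.evaluate_rasa_pooled(r_pairs)
        r_f, mae_f = rasa.evaluate_rasa_pooled(f_pairs)
        results.append({
            "seed": seed,
            "template_r": r_t, "template_mae": mae_t,
            "regression_r": r_r, "regression_mae": mae_r,
            "fused_r": r_f, "fused_mae": mae_f,
        })
    return results
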