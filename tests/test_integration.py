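"""Cluster integration: map validation, labeled datasets, corrections."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mixture import cluster_montage as cm
from mixture import integration as integ
from mixture import ssl_encoder as ssl
from mixture import synthetic_cohort as synth
from mixture import tiler


def _scheme(names=("A", "B", "other")):
    return integ.FindingScheme("20x", tuple(names))


def _model(k):
    return cm.ClusterModel(k=k, centroids=np.zeros((k, 2)),
                           assignments=np.empty(0, int), inertia=0.0, seed=0)


def _tileset(images):
    cfg = tiler.TilingConfig(tile_size=images.shape[1],
                             max_tiles_per_slide=None)
    tiles = [tiler.Tile("s", "20x", i, 0, 0, 0 + i, image=img)
             for i, img in enumerate(images)]
    return tiler.TileSet(tiles, cfg)


class TestIntegrationMapIO:
    def test_valid_map_round_trips(self, tmp_path):
        scheme = _scheme()
        imap = integ.IntegrationMap(scheme, {0: "A", 1: "B", 2: integ.EXCLUDED,
                                             3: "other"}, note="review 1")
        p = integ.save_integration_map(imap, tmp_path / "map.json")
        back = integ.load_integration_map(p, _model(4), scheme)
        assert back.entries == imap.entries
        assert back.note == "review 1"

    def test_missing_cluster_named_in_error(self, tmp_path):
        imap = integ.IntegrationMap(_scheme(), {i: "A" for i in range(8) if i != 7})
        p = integ.save_integration_map(imap, tmp_path / "m.json")
        with pytest.raises(ValueError, match=r"\[7\]"):
            integ.load_integration_map(p, _model(8), _scheme())

    def test_unknown_class_rejected(self, tmp_path):
        imap = integ.IntegrationMap(_scheme(), {0: "A"})
        p = integ.save_integration_map(imap, tmp_path / "m.json")
        (tmp_path / "bad.json").write_text(
            p.read_text().replace('"A"', '"fibrosis!!"'))
        with pytest.raises(ValueError, match="fibrosis!!"):
            integ.load_integration_map(tmp_path / "bad.json", _model(1), _scheme())

    def test_duplicate_cluster_id_rejected(self, tmp_path):
        (tmp_path / "dup.json").write_text(
            '{"magnification_level": "20x", "classes": ["A", "other"],'
            ' "entries": {"0": "A", "00": "A"}}')
        with pytest.raises(ValueError, match="duplicate"):
            integ.load_integration_map(tmp_path / "dup.json", _model(1),
                                       _scheme(("A", "other")))

    def test_scheme_requires_other_and_unique_names(self):
        with pytest.raises(ValueError):
            integ.FindingScheme("5x", ("A", "B"))
        with pytest.raises(ValueError):
            integ.FindingScheme("5x", ("A", "A", "other"))

    def test_default_schemes_match_published_finding_lists(self):
        s5 = integ.default_scheme("5x")
        assert "complete normal" in s5.class_names
        assert "pale" in s5.class_names
        assert s5.special_excluded_from_frequencies == ("complete normal",)
        s20 = integ.default_scheme("20x")
        assert "fibroblastic foci" in s20.class_names
        assert "other" in s20.class_names
        assert len(integ.default_scheme("2.5x").class_names) == 4


class TestBuildLabeledDataset:
    def test_excluded_clusters_dropped(self):
        imgs = np.zeros((60, 16, 16, 3), dtype=np.uint8)
        ts = _tileset(imgs)
        assign = np.repeat([0, 1, 2], [10, 20, 30])
        imap = integ.IntegrationMap(_scheme(), {0: "A", 1: "A",
                                                2: integ.EXCLUDED})
        ds = integ.build_labeled_dataset(ts, assign, imap)
        assert len(ds) == 30
        assert set(ds.labels) == {"A"}

    def test_all_excluded_gives_empty_dataset(self):
        ts = _tileset(np.zeros((10, 16, 16, 3), dtype=np.uint8))
        imap = integ.IntegrationMap(_scheme(), {0: integ.EXCLUDED})
        ds = integ.build_labeled_dataset(ts, np.zeros(10, int), imap)
        assert len(ds) == 0

    def test_other_is_a_trainable_label(self):
        ts = _tileset(np.zeros((10, 16, 16, 3), dtype=np.uint8))
        imap = integ.IntegrationMap(_scheme(), {0: "other"})
        ds = integ.build_labeled_dataset(ts, np.zeros(10, int), imap)
        assert ds.class_counts()["other"] == 10

    def test_label_conservation(self):
        sizes = [7, 13, 21, 9]
        ts = _tileset(np.zeros((sum(sizes), 16, 16, 3), dtype=np.uint8))
        assign = np.repeat(np.arange(4), sizes)
        imap = integ.IntegrationMap(_scheme(), {0: "A", 1: "B",
                                                2: integ.EXCLUDED, 3: "B"})
        ds = integ.build_labeled_dataset(ts, assign, imap)
        assert len(ds) == 7 + 13 + 9
        assert ds.class_counts() == {"A": 7, "B": 22, "other": 0}


class TestCorrections:
    def _dataset(self):
        imgs = np.zeros((50, 16, 16, 3), dtype=np.uint8)
        return integ.LabeledTileDataset(
            [f"t{i}" for i in range(50)], imgs,
            ["A"] * 25 + ["B"] * 25, ["principal"] * 50, _scheme())

    def test_relabel_shifts_counts_exactly(self):
        ds = self._dataset()
        corr = pd.DataFrame({"tile_id": [f"t{i}" for i in range(5)],
                             "action": ["relabel"] * 5, "new_class": ["B"] * 5})
        out, audit = integ.apply_corrections(ds, corr)
        assert out.class_counts() == {"A": 20, "B": 30, "other": 0}
        assert len(audit) == 5 and set(audit["action"]) == {"relabel"}

    def test_remove_shrinks_dataset(self):
        ds = self._dataset()
        corr = pd.DataFrame({"tile_id": ["t0", "t30"],
                             "action": ["remove"] * 2, "new_class": ["", ""]})
        out, _ = integ.apply_corrections(ds, corr)
        assert len(out) == 48

    def test_empty_corrections_identity(self):
        ds = self._dataset()
        out, audit = integ.apply_corrections(
            ds, pd.DataFrame(columns=["tile_id", "action", "new_class"]))
        assert out.labels == ds.labels and len(audit) == 0

    def test_unknown_tile_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            integ.apply_corrections(self._dataset(), pd.DataFrame(
                {"tile_id": ["nope"], "action": ["remove"], "new_class": [""]}))


class TestEnrichPerCase:
    def test_independent_models_and_additivity(self, trained_encoder,
                                               texture_bank):
        tiles, labels, _ = texture_bank
        sets = {f"case_{j}": _tileset(tiles[40 * j:40 * (j + 1)])
                for j in range(3)}
        models, montages = integ.enrich_per_case(sets, trained_encoder,
                                                 k_per_case=4, seed=0)
        assert set(models) == set(sets)
        scheme = _scheme(("A", "B", "other"))
        total = 0
        merged = integ.LabeledTileDataset([], np.empty((0, 32, 32, 3), np.uint8),
                                          [], [], scheme)
        for j, (cid, model) in enumerate(sorted(models.items())):
            imap = integ.IntegrationMap(scheme,
                                        {c: "A" for c in range(model.k)})
            part = integ.build_labeled_dataset(sets[cid], model.assignments,
                                               imap, source="supplemental")
            part.tile_keys = [f"{cid}:{k}" for k in part.tile_keys]
            merged = merged.merged_with(part)
            total += len(part)
        assert len(merged) == total == 120

    def test_undersized_case_skipped(self, trained_encoder, texture_bank):
        tiles, _, _ = texture_bank
        sets = {"small": _tileset(tiles[:3]), "ok": _tileset(tiles[:40])}
        models, _ = integ.enrich_per_case(sets, trained_encoder,
                                          k_per_case=10, seed=0)
        assert set(models) == {"ok"}

    def test_pure_case_clusters_agree(self, trained_encoder):
        # one pure texture, k=2: both clusters map to the same class
        c = synth.default_texture_classes(1)[0]
        imgs = np.stack([synth.make_texture(c, 32, seed=s) for s in range(40)])
        models, _ = integ.enrich_per_case({"case": _tileset(imgs)},
                                          trained_encoder, k_per_case=2, seed=0)
        truth = np.zeros(40, int)
        imap = integ.oracle_integration_map(models["case"].assignments, truth,
                                            _scheme(), class_names=["A"])
        assert set(imap.entries.values()) == {"A"}


class TestOracleIntegration:
    def test_label_purity_tracks_cluster_quality(self, texture_features,
                                                 texture_bank):
        tiles, labels, classes = texture_bank
        model = cm.fit_kmeans(texture_features, 4, seed=0)
        ari = adjusted_rand_score(labels, model.assignments)
        names = [c.name for c in classes]
        scheme = integ.FindingScheme("20x", tuple(names + ["other"]))
        imap = integ.oracle_integration_map(model.assignments, labels, scheme,
                                            class_names=names)
        mapped = np.array([names.index(imap.label_of(a))
                           for a in model.assignments])
        purity = (mapped == labels).mean()
        if ari >= 0.8:
            assert purity >= 0.9
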