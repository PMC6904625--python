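"""Contact detection, contact summaries and network components."""

from __future__ import annotations

import numpy as np
import pytest

from stromametry import (
    ContactRecord,
    InstanceInfo,
    InstanceMap,
    LabelVolume,
    VesicleMeasurement,
    compare_contact_sizes,
    contact_summary,
    detect_contacts,
    mann_whitney,
    stellate_networks,
)
from stromametry.categories import NAME_TO_CODE

SPACING = (50.0, 14.0, 14.0)


def _scene(pairs):
    """Tiny labeled scene: ``pairs`` is {(z,y,x): (category, instance)}."""
    vox = np.full((6, 8, 8), NAME_TO_CODE["stroma_ecm"], dtype=np.int16)
    inst = np.zeros((6, 8, 8), dtype=np.int32)
    table = {}
    for (z, y, x), (category, iid) in pairs.items():
        vox[z, y, x] = NAME_TO_CODE[category]
        inst[z, y, x] = iid
        table[iid] = InstanceInfo(category)
    return (
        LabelVolume(vox, SPACING),
        InstanceMap(inst, SPACING, table),
    )


class TestDetectContacts:
    def test_face_adjacent_stellate_recorded(self):
        vol, imap = _scene(
            {(2, 3, 3): ("vesicle", 1), (2, 3, 4): ("stellate_cell", 2)}
        )
        (rec,) = detect_contacts(vol, imap)
        assert rec.partners == {"stellate_cell"}
        assert rec.any_stromal_cell_contact

    def test_embedded_vesicle_has_no_partners(self):
        vol, imap = _scene({(2, 3, 3): ("vesicle", 1)})
        (rec,) = detect_contacts(vol, imap)
        assert rec.partners == frozenset()
        assert not rec.any_stromal_cell_contact

    def test_corner_adjacency_counts_under_26_connectivity(self):
        vol, imap = _scene(
            {(2, 3, 3): ("vesicle", 1), (3, 4, 4): ("macrophage", 2)}
        )
        (rec26,) = detect_contacts(vol, imap, connectivity=26)
        assert rec26.partners == {"macrophage"}
        (rec6,) = detect_contacts(vol, imap, connectivity=6)
        assert rec6.partners == frozenset()

    def test_vesicle_vesicle_contact_is_mutual(self):
        vol, imap = _scene({(2, 3, 3): ("vesicle", 1), (2, 3, 4): ("vesicle", 2)})
        recs = {r.vesicle_id: r for r in detect_contacts(vol, imap)}
        assert recs[1].partners == {"vesicle"}
        assert recs[2].partners == {"vesicle"}

    def test_unknown_vesicle_id_rejected(self):
        vol, imap = _scene({(2, 3, 3): ("vesicle", 1)})
        with pytest.raises(ValueError):
            detect_contacts(vol, imap, vesicle_ids=[9])

    def test_phantom_contact_fraction_equals_ground_truth(self, small_phantom):
        vol, imap, truth = small_phantom
        recs = detect_contacts(vol, imap)
        detected = sum(1 for r in recs if "stellate_cell" in r.partners)
        assert detected == truth.n_contact_vesicles


class TestContactSummary:
    @staticmethod
    def _record(vid, partners):
        partners = frozenset(partners)
        return ContactRecord(
            vid, partners, bool(partners & {"stellate_cell", "macrophage"})
        )

    def test_published_tally_rounds_to_59_and_63(self):
        """16 stellate + 1 macrophage-only of 27 vesicles: 59% stellate,
        63% any stromal cell."""
        records = (
            [self._record(i, {"stellate_cell"}) for i in range(16)]
            + [self._record(16, {"macrophage"})]
            + [self._record(i, set()) for i in range(17, 27)]
        )
        s = contact_summary(records)
        assert s["pct_stellate_contact"] == 59
        assert s["pct_any_stromal_contact"] == 63

    def test_no_contacts_at_all(self):
        s = contact_summary([self._record(i, set()) for i in range(5)])
        assert s["pct_stellate_contact"] == 0

    def test_one_of_three_rounds_to_33(self):
        records = [
            self._record(0, {"stellate_cell"}),
            self._record(1, set()),
            self._record(2, set()),
        ]
        assert contact_summary(records)["pct_stellate_contact"] == 33

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            contact_summary([])


class TestCompareContactSizes:
    @staticmethod
    def _measurement(vid, length_nm):
        return VesicleMeasurement(
            instance_id=vid,
            extent_z=length_nm,
            extent_y=length_nm / 2,
            extent_x=length_nm / 2,
            length=length_nm,
            width=length_nm / 2,
            ratio=0.5,
        )

    def _build(self, contact_lengths_um, free_lengths_um):
        ms, recs = [], []
        for i, lu in enumerate(list(contact_lengths_um) + list(free_lengths_um)):
            contact = i < len(contact_lengths_um)
            ms.append(self._measurement(i + 1, lu * 1000))
            partners = frozenset({"stellate_cell"}) if contact else frozenset()
            recs.append(ContactRecord(i + 1, partners, contact))
        return ms, recs

    def test_separated_triples_exact_p(self):
        ms, recs = self._build([4, 5, 6], [1, 2, 3])
        out = compare_contact_sizes(ms, recs)
        assert out.test.p_value == pytest.approx(0.1)
        assert out.n_contact == 3 and out.n_no_contact == 3
        assert out.median_contact_um == pytest.approx(5.0)

    def test_identical_groups_not_significant(self):
        ms, recs = self._build([1, 2, 3], [1, 2, 3])
        assert compare_contact_sizes(ms, recs).test.p_value > 0.9

    def test_missing_record_rejected(self):
        ms, recs = self._build([1, 2], [3, 4])
        with pytest.raises(ValueError):
            compare_contact_sizes(ms, recs[:-1])

    def test_power_when_contact_vesicles_twice_larger(self):
        """18 contact vs 9 free vesicles with a doubled contact median:
        the rank test is significant at 0.05 in most replicates."""
        hits = 0
        reps = 200
        for seed in range(reps):
            r = np.random.default_rng(seed)
            contact = 2 * 2750 * np.exp(0.7 * r.standard_normal(18)) / 1000
            free = 2750 * np.exp(0.7 * r.standard_normal(9)) / 1000
            if mann_whitney(contact, free).p_value < 0.05:
                hits += 1
        assert hits / reps > 0.5


class TestStellateNetworks:
    def _network_scene(self, cells):
        """cells: list of (instance_id, network_id, voxel list)."""
        vox = np.zeros((6, 10, 10), dtype=np.int32)
        table = {}
        for iid, net, voxels in cells:
            for z, y, x in voxels:
                vox[z, y, x] = iid
            table[iid] = InstanceInfo("stellate_cell", net)
        return InstanceMap(vox, SPACING, table)

    def test_components_three_plus_isolated(self):
        imap = self._network_scene(
            [
                (1, 1, [(1, 1, 1)]),
                (2, 1, [(1, 1, 2)]),
                (3, 1, [(1, 2, 2)]),
                (4, 2, [(4, 8, 8)]),
            ]
        )
        s = stellate_networks(imap)
        assert sorted(s.sizes) == [1, 3]
        assert s.mean == pytest.approx(2.0)

    def test_chain_forms_single_network(self):
        imap = self._network_scene(
            [(i, 1, [(1, 1, i)]) for i in range(1, 6)]
        )
        s = stellate_networks(imap)
        assert s.sizes == (5,)
        assert s.n_networks == 1

    def test_sizes_partition_all_cells(self, small_phantom):
        _, imap, truth = small_phantom
        s = stellate_networks(imap)
        assert sum(s.sizes) == len(imap.ids_of_category("stellate_cell"))
        assert sorted(s.sizes) == sorted(truth.network_sizes.values())

    def test_no_stellate_instances_rejected(self):
        imap = InstanceMap(
            np.zeros((3, 3, 3), dtype=np.int32), SPACING, {}
        )
        with pytest.raises(ValueError):
            stellate_networks(imap)
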