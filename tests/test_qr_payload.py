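import numpy as np
import pytest
from random import Random

import medseal as ms
from medseal.errors import CapacityError, KeyAuthError, QRDecodeError
from medseal.qr_payload import (QR_CAPACITY_BYTES, format_arnold_text,
                                parse_arnold_text)
from medseal.rdh_pee import PEEParams, PEERecord

import base64


def make_params(locmap=(), arnold_text="8 × 8 4"):
    rng = np.random.default_rng(0)
    return ms.ProtectedParams(
        arnold_text=arnold_text,
        key_tile=ms.Tile(160, 160, 160),
        pee_record=PEERecord(params=PEEParams(p=-5, q=5),
                             payload_bits=204800,
                             location_map=tuple(locmap)),
        embeddable_mask=rng.random((64, 64)) > 0.3,
        scramble_mask=rng.random((64, 64)) > 0.2,
        image_shape=(512, 512),
    )


class TestBasicInfo:
    def test_text_round_trip(self, basic_info):
        assert ms.BasicInfo.from_text(basic_info.to_text()) == basic_info

    def test_field_order_is_fixed(self, basic_info):
        lines = basic_info.to_text().split("\n")
        assert lines[0].startswith("Hospital:")
        assert lines[-1] == "Image type: brain CT"

    def test_empty_fields_allowed(self):
        empty = ms.BasicInfo()
        assert ms.BasicInfo.from_text(empty.to_text()) == empty


class TestArnoldText:
    def test_worked_parameter_string(self):
        assert format_arnold_text(8, 4) == "8 × 8 4"
        assert parse_arnold_text("8 × 8 4") == (8, 4)

    def test_ascii_x_accepted(self):
        assert parse_arnold_text("8 x 8 4") == (8, 4)

    def test_rectangular_rejected(self):
        with pytest.raises(ValueError):
            parse_arnold_text("8 × 16 4")


class TestProtectedParams:
    def test_byte_round_trip(self):
        p = make_params(locmap=[(1, 2), (500, 511)])
        q = ms.ProtectedParams.from_bytes(p.to_bytes())
        assert q.arnold_text == p.arnold_text
        assert q.key_tile == p.key_tile
        assert q.pee_record == p.pee_record
        assert np.array_equal(q.embeddable_mask, p.embeddable_mask)
        assert np.array_equal(q.scramble_mask, p.scramble_mask)
        assert q.image_shape == p.image_shape

    def test_corrupted_bytes_rejected(self):
        with pytest.raises(KeyAuthError):
            ms.ProtectedParams.from_bytes(b"garbage")


class TestHybridCrypto:
    def test_round_trip_of_worked_plaintext(self, keypair):
        pub, priv = keypair
        p = make_params(arnold_text="8 × 8 4")
        ct = ms.encrypt_params(p, pub, rng=Random(1))
        out = ms.decrypt_params(ct, priv)
        assert out.arnold_text == "8 × 8 4"
        assert out.pee_record == p.pee_record

    def test_wrong_key_fails_closed(self, keypair):
        pub, _ = keypair
        _, other_priv = ms.generate_keypair(bits=1024, seed=99)
        ct = ms.encrypt_params(make_params(), pub, rng=Random(2))
        with pytest.raises(KeyAuthError):
            ms.decrypt_params(ct, other_priv)

    def test_tampered_ciphertext_fails_authentication(self, keypair):
        pub, priv = keypair
        ct = ms.encrypt_params(make_params(), pub, rng=Random(3))
        raw = bytearray(base64.b64decode(ct))
        raw[-40] ^= 0x01
        with pytest.raises(KeyAuthError):
            ms.decrypt_params(base64.b64encode(bytes(raw)).decode(), priv)

    def test_keypair_generation_is_seed_deterministic(self):
        a = ms.generate_keypair(bits=1024, seed=5)
        b = ms.generate_keypair(bits=1024, seed=5)
        assert a == b

    def test_key_file_round_trip(self, keypair, tmp_path):
        pub, priv = keypair
        ms.save_key(pub, tmp_path / "pub.json")
        ms.save_key(priv, tmp_path / "priv.json")
        assert ms.load_public_key(tmp_path / "pub.json") == pub
        assert ms.load_private_key(tmp_path / "priv.json") == priv
        with pytest.raises(KeyAuthError):
            ms.load_private_key(tmp_path / "pub.json")


class TestSymbol:
    def payloads(self, keypair, n):
        pub, _ = keypair
        out = []
        for i in range(n):
            rng = Random(i)
            info = ms.BasicInfo(hospital=f"hospital-{i}",
                                patient_number=str(10_000 + i),
                                image_type="CT")
            ct = ms.encrypt_params(make_params(), pub, rng=rng)
            out.append(ms.QRPayload(basic=info, ciphertext=ct))
        return out

    def test_render_decode_round_trip_many(self, keypair):
        for payload in self.payloads(keypair, 20):
            assert ms.decode_qr(ms.render_qr(payload)) == payload

    def test_symbol_geometry_and_binarization(self, keypair):
        qr = ms.render_qr(self.payloads(keypair, 1)[0])
        assert qr.shape == (160, 160)
        assert qr.size == 25_600
        assert set(np.unique(qr)) <= {0, 255}

    def test_basic_info_readable_without_private_key(self, keypair):
        payload = self.payloads(keypair, 1)[0]
        decoded = ms.decode_qr(ms.render_qr(payload))
        assert decoded.basic == payload.basic  # no key used anywhere

    def test_scrambled_symbol_fails(self, keypair):
        qr = ms.render_qr(self.payloads(keypair, 1)[0])
        scrambled = qr.reshape(20, 8, 20, 8).transpose(0, 2, 1, 3)
        scrambled = np.ascontiguousarray(
            scrambled.reshape(400, 8, 8)[::-1]).reshape(20, 20, 8, 8)
        scrambled = scrambled.transpose(0, 2, 1, 3).reshape(160, 160)
        with pytest.raises(QRDecodeError):
            ms.decode_qr(scrambled)

    def test_natural_image_block_fails(self, phantom1):
        with pytest.raises(QRDecodeError):
            ms.decode_qr(phantom1[:160, :160])

    def test_oversized_payload_raises_capacity_error(self, keypair):
        payload = ms.QRPayload(
            basic=ms.BasicInfo(hospital="x" * (QR_CAPACITY_BYTES + 10)),
            ciphertext="")
        with pytest.raises(CapacityError):
            ms.render_qr(payload)

    def test_locate_finds_off_grid_symbol(self, keypair, phantom1):
        payload = self.payloads(keypair, 1)[0]
        img = ms.write_block(phantom1, ms.Tile(37, 91, 160),
                             ms.render_qr(payload))
        tile, found = ms.locate_qr(img)
        assert tile == ms.Tile(37, 91, 160)
        assert found == payload
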