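# Default FRETfluor construct registry.
#
# Four design families share the same Cy3/Cy5 chemistry but differ in the
# local DNA environment of the donor, which sets the donor-only lifetime
# (ns) and green brightness (counts ms^-1 uW^-1):
#   AB     - baseline duplex, internal Cy3/Cy5 with unpaired opposing bases
#   AB_sk  - "skip" complement lacking the unpaired bases (shorter lifetime)
#   A_cB   - extra 5'-tethered "cap" Cy3 (brighter, shortest net lifetime)
#   AB_in  - extra internal Cy3 on the bridge side (brightest)
# Donor-acceptor spacing N (base pairs) tunes the FRET efficiency E; entries
# without an explicit E get E from the distance model below.
fret_model:
  R0_nm: 5.4
  rise_nm: 0.34
families:
  - name: AB
    donor_lifetime_0_ns: 1.60
    donor_brightness_0: 0.31
  - name: AB_sk
    donor_lifetime_0_ns: 1.25
    donor_brightness_0: 0.26
  - name: A_cB
    donor_lifetime_0_ns: 1.07
    donor_brightness_0: 0.40
  - name: AB_in
    donor_lifetime_0_ns: 1.51
    donor_brightness_0: 0.560
constructs:
  # 15 AB constructs, 6 <= N <= 20
  - {label: AB6,  family: AB, N: 6}
  - {label: AB7,  family: AB, N: 7}
  - {label: AB8,  family: AB, N: 8}
  - {label: AB9,  family: AB, N: 9}
  - {label: AB10, family: AB, N: 10}
  - {label: AB11, family: AB, N: 11}
  - {label: AB12, family: AB, N: 12}
  - {label: AB13, family: AB, N: 13}
  - {label: AB14, family: AB, N: 14}
  - {label: AB15, family: AB, N: 15}
  - {label: AB16, family: AB, N: 16}
  - {label: AB17, family: AB, N: 17}
  - {label: AB18, family: AB, N: 18}
  - {label: AB19, family: AB, N: 19}
  - {label: AB20, family: AB, N: 20}
  # 8 AB_sk constructs
  - {label: AB_sk6,  family: AB_sk, N: 6}
  - {label: AB_sk7,  family: AB_sk, N: 7}
  - {label: AB_sk8,  family: AB_sk, N: 8}
  - {label: AB_sk9,  family: AB_sk, N: 9}
  - {label: AB_sk10, family: AB_sk, N: 10}
  - {label: AB_sk11, family: AB_sk, N: 11}
  - {label: AB_sk12, family: AB_sk, N: 12}
  - {label: AB_sk13, family: AB_sk, N: 13}
  # 9 A_cB constructs
  - {label: A_cB6,  family: A_cB, N: 6}
  - {label: A_cB7,  family: A_cB, N: 7}
  - {label: A_cB8,  family: A_cB, N: 8}
  - {label: A_cB9,  family: A_cB, N: 9}
  - {label: A_cB10, family: A_cB, N: 10}
  - {label: A_cB11, family: A_cB, N: 11}
  - {label: A_cB12, family: A_cB, N: 12}
  - {label: A_cB13, family: A_cB, N: 13}
  - {label: A_cB14, family: A_cB, N: 14}
  # 9 AB_in constructs
  - {label: AB_in6,  family: AB_in, N: 6}
  - {label: AB_in7,  family: AB_in, N: 7}
  - {label: AB_in8,  family: AB_in, N: 8}
  - {label: AB_in9,  family: AB_in, N: 9}
  - {label: AB_in10, family: AB_in, N: 10}
  - {label: AB_in11, family: AB_in, N: 11}
  - {label: AB_in12, family: AB_in, N: 12}
  - {label: AB_in13, family: AB_in, N: 13}
  - {label: AB_in14, family: AB_in, N: 14}
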