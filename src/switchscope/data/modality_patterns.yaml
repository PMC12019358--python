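# Regular-expression table mapping drug product names (and free-text drug
# mentions) to contraceptive modalities. Matching is case-insensitive.
# `excluded` patterns are tried first and mark non-drug contraceptives,
# emergency contraception and pH modulators for removal from the cohort.
# Modality groups are tried in the order listed: specific delivery-route
# patterns before the broad oral patterns, so combination products that
# mention an active ingredient shared across routes resolve by route.
excluded:
  - emergency
  - "plan b"
  - ulipristal
  - ella\b
  - levonorgestrel\s+1\.5
  - condom
  - diaphragm
  - cervical cap
  - spermicide
  - nonoxynol
  - ph modulator
  - phexxi
modalities:
  IUD:
    - intrauterine
    - \biud\b
    - mirena
    - kyleena
    - skyla
    - liletta
    - paragard
    - copper\s+(iud|coil|t\b)
  Implant:
    - subdermal
    - implant
    - nexplanon
    - implanon
  Injectable:
    - inject
    - intramuscular
    - subcutaneous
    - depo[-\s]?provera
    - \bdepo\b
    - medroxyprogesterone
  Transdermal:
    - transdermal
    - \bpatch\b
    - xulane
    - twirla
    - ortho\s?evra
  Intravaginal:
    - vaginal ring
    - intravaginal
    - nuvaring
    - annovera
    - eluryng
    - \bring\b
  Oral:
    - oral
    - tablet
    - \bpills?\b
    - norethindrone
    - camila
    - heather
    - errin
    - sprintec
    - \byaz\b
    - yasmin
    - junel
    - loestrin
    - \bapri\b
    - ortho[-\s]?tri[-\s]?cyclen
    - drospirenone
    - norgestimate
    - desogestrel
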