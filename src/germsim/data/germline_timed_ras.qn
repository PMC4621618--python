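qn: 1
variables:
- {name: DELTA, max: 1, input: true}
- {name: RASinput, max: 1, input: true}
- {name: MSP, max: 1, input: true}
- {name: RASdown, max: 1, input: true}
- name: NOTCH
  max: 1
  activators: [DELTA]
- name: VAB1
  max: 1
  activators: [MSP]
- {name: RAS, max: 1, target: 'min((1 - RASdown), max(RAS, RASinput, VAB1))'}
- name: MAPK
  max: 1
  activators: [RAS]
- name: CEP1
  max: 1
  activators: [MAPK]
- name: EGL1
  max: 1
  activators: [CEP1]
- name: CED3
  max: 1
  activators: [EGL1]
- {name: CCLICENSE, max: 1, target: 'min(CCLICENSE, (1 - NOTCH))'}
- {name: CYCB, max: 1, target: 'min(CCLICENSE, (1 - APC))'}
- {name: APC, max: 1, target: 'min(CCLICENSE, CYCB)'}
- name: MITOSIS
  max: 1
  activators: [NOTCH]
- {name: PACHYTENE, max: 1, target: (1 - NOTCH)}
- {name: DIPLOTENE, max: 1, target: 'min((1 - NOTCH), max(DIPLOTENE, MAPK))'}
- {name: DIAKINESIS, max: 1, target: 'min((1 - NOTCH), max(DIAKINESIS, min(DIPLOTENE,
    (1 - MAPK))))'}
- {name: MATURATION, max: 1, target: 'min((1 - NOTCH), max(MATURATION, min(DIAKINESIS,
    MAPK, VAB1)))'}
name: germline-timed-ras
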