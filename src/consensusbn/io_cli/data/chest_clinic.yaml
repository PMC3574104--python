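format: consensusbn-network/1
weight: 1
variables:
- name: asia
  states: [yes_, no_]
- name: bronc
  states: [yes_, no_]
- name: dysp
  states: [yes_, no_]
- name: either
  states: [yes_, no_]
- name: lung
  states: [yes_, no_]
- name: smoke
  states: [yes_, no_]
- name: tub
  states: [yes_, no_]
- name: xray
  states: [yes_, no_]
edges:
- {from: asia, to: tub}
- {from: bronc, to: dysp}
- {from: either, to: dysp}
- {from: either, to: xray}
- {from: lung, to: either}
- {from: smoke, to: bronc}
- {from: smoke, to: lung}
- {from: tub, to: either}
cpts:
  asia:
    parents: []
    rows:
    - {given: {}, p: [0.01, 0.99]}
  tub:
    parents: [asia]
    rows:
    - {given: {asia: yes_}, p: [0.05, 0.95]}
    - {given: {asia: no_}, p: [0.01, 0.99]}
  smoke:
    parents: []
    rows:
    - {given: {}, p: [0.5, 0.5]}
  lung:
    parents: [smoke]
    rows:
    - {given: {smoke: yes_}, p: [0.1, 0.9]}
    - {given: {smoke: no_}, p: [0.01, 0.99]}
  bronc:
    parents: [smoke]
    rows:
    - {given: {smoke: yes_}, p: [0.6, 0.4]}
    - {given: {smoke: no_}, p: [0.3, 0.7]}
  either:
    parents: [lung, tub]
    rows:
    - {given: {lung: yes_, tub: yes_}, p: [1.0, 0.0]}
    - {given: {lung: yes_, tub: no_}, p: [1.0, 0.0]}
    - {given: {lung: no_, tub: yes_}, p: [1.0, 0.0]}
    - {given: {lung: no_, tub: no_}, p: [0.0, 1.0]}
  xray:
    parents: [either]
    rows:
    - {given: {either: yes_}, p: [0.98, 0.02]}
    - {given: {either: no_}, p: [0.05, 0.95]}
  dysp:
    parents: [bronc, either]
    rows:
    - {given: {bronc: yes_, either: yes_}, p: [0.9, 0.1]}
    - {given: {bronc: yes_, either: no_}, p: [0.8, 0.2]}
    - {given: {bronc: no_, either: yes_}, p: [0.7, 0.3]}
    - {given: {bronc: no_, either: no_}, p: [0.1, 0.9]}
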