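graph [
  name "synthetic-20"
  node [
    id 0
    label "n01"
  ]
  node [
    id 1
    label "n02"
  ]
  node [
    id 2
    label "n03"
  ]
  node [
    id 3
    label "n04"
  ]
  node [
    id 4
    label "n05"
  ]
  node [
    id 5
    label "n06"
  ]
  node [
    id 6
    label "n07"
  ]
  node [
    id 7
    label "n08"
  ]
  node [
    id 8
    label "n09"
  ]
  node [
    id 9
    label "n10"
  ]
  node [
    id 10
    label "n11"
  ]
  node [
    id 11
    label "n12"
  ]
  node [
    id 12
    label "n13"
  ]
  node [
    id 13
    label "n14"
  ]
  node [
    id 14
    label "n15"
  ]
  node [
    id 15
    label "n16"
  ]
  node [
    id 16
    label "n17"
  ]
  node [
    id 17
    label "n18"
  ]
  node [
    id 18
    label "n19"
  ]
  node [
    id 19
    label "n20"
  ]
  node [
    id 20
    label "n21"
  ]
  node [
    id 21
    label "n22"
  ]
  node [
    id 22
    label "n23"
  ]
  node [
    id 23
    label "n24"
  ]
  node [
    id 24
    label "n25"
  ]
  node [
    id 25
    label "n26"
  ]
  node [
    id 26
    label "n27"
  ]
  node [
    id 27
    label "n28"
  ]
  node [
    id 28
    label "n29"
  ]
  node [
    id 29
    label "n30"
  ]
  node [
    id 30
    label "n31"
  ]
  node [
    id 31
    label "n32"
  ]
  node [
    id 32
    label "n33"
  ]
  node [
    id 33
    label "n34"
  ]
  edge [
    source 0
    target 1
  ]
  edge [
    source 0
    target 3
  ]
  edge [
    source 0
    target 7
  ]
  edge [
    source 0
    target 13
  ]
  edge [
    source 0
    target 14
  ]
  edge [
    source 0
    target 5
  ]
  edge [
    source 0
    target 9
  ]
  edge [
    source 1
    target 2
  ]
  edge [
    source 1
    target 4
  ]
  edge [
    source 1
    target 8
  ]
  edge [
    source 1
    target 15
  ]
  edge [
    source 1
    target 31
  ]
  edge [
    source 1
    target 20
  ]
  edge [
    source 1
    target 21
  ]
  edge [
    source 1
    target 32
  ]
  edge [
    source 2
    target 5
  ]
  edge [
    source 2
    target 10
  ]
  edge [
    source 2
    target 29
  ]
  edge [
    source 2
    target 16
  ]
  edge [
    source 2
    target 19
  ]
  edge [
    source 2
    target 24
  ]
  edge [
    source 2
    target 25
  ]
  edge [
    source 3
    target 13
  ]
  edge [
    source 3
    target 29
  ]
  edge [
    source 3
    target 33
  ]
  edge [
    source 4
    target 9
  ]
  edge [
    source 4
    target 11
  ]
  edge [
    source 4
    target 12
  ]
  edge [
    source 4
    target 15
  ]
  edge [
    source 4
    target 27
  ]
  edge [
    source 4
    target 28
  ]
  edge [
    source 4
    target 29
  ]
  edge [
    source 5
    target 6
  ]
  edge [
    source 5
    target 18
  ]
  edge [
    source 5
    target 24
  ]
  edge [
    source 5
    target 29
  ]
  edge [
    source 6
    target 25
  ]
  edge [
    source 6
    target 30
  ]
  edge [
    source 7
    target 11
  ]
  edge [
    source 7
    target 21
  ]
  edge [
    source 7
    target 23
  ]
  edge [
    source 8
    target 27
  ]
  edge [
    source 8
    target 13
  ]
  edge [
    source 8
    target 22
  ]
  edge [
    source 8
    target 29
  ]
  edge [
    source 9
    target 21
  ]
  edge [
    source 9
    target 24
  ]
  edge [
    source 10
    target 16
  ]
  edge [
    source 10
    target 17
  ]
  edge [
    source 10
    target 22
  ]
  edge [
    source 11
    target 32
  ]
  edge [
    source 12
    target 22
  ]
  edge [
    source 12
    target 14
  ]
  edge [
    source 12
    target 24
  ]
  edge [
    source 12
    target 26
  ]
  edge [
    source 13
    target 19
  ]
  edge [
    source 14
    target 23
  ]
  edge [
    source 14
    target 15
  ]
  edge [
    source 14
    target 20
  ]
  edge [
    source 14
    target 26
  ]
  edge [
    source 14
    target 31
  ]
  edge [
    source 15
    target 28
  ]
  edge [
    source 15
    target 20
  ]
  edge [
    source 15
    target 27
  ]
  edge [
    source 16
    target 17
  ]
  edge [
    source 16
    target 18
  ]
  edge [
    source 16
    target 32
  ]
  edge [
    source 17
    target 28
  ]
  edge [
    source 18
    target 20
  ]
  edge [
    source 18
    target 26
  ]
  edge [
    source 19
    target 32
  ]
  edge [
    source 19
    target 20
  ]
  edge [
    source 19
    target 27
  ]
  edge [
    source 20
    target 30
  ]
  edge [
    source 20
    target 32
  ]
  edge [
    source 22
    target 25
  ]
  edge [
    source 22
    target 27
  ]
  edge [
    source 26
    target 33
  ]
]
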