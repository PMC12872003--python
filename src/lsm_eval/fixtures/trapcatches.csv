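site,week_index,genus,sex,count
Abaam,1,Aedes,female,1
Abaam,1,Anopheles,female,1
Abaam,1,Culex,female,32
Abaam,1,Culex,male,11
Abaam,1,non_target,unknown,7
Abaam,2,Aedes,female,1
Abaam,2,Anopheles,female,1
Abaam,2,Culex,female,20
Abaam,2,Culex,male,7
Abaam,2,non_target,unknown,7
Abaam,3,Aedes,female,1
Abaam,3,Anopheles,female,1
Abaam,3,Culex,female,15
Abaam,3,Culex,male,5
Abaam,3,non_target,unknown,7
Abaam,4,Aedes,female,1
Abaam,4,Culex,female,14
Abaam,4,Culex,male,5
Abaam,4,non_target,unknown,7
Abaam,5,Aedes,female,1
Abaam,5,Culex,female,13
Abaam,5,Culex,male,4
Abaam,5,non_target,unknown,7
Abaam,6,Aedes,female,1
Abaam,6,Culex,female,40
Abaam,6,Culex,male,13
Abaam,6,non_target,unknown,7
Abaam,7,Culex,female,19
Abaam,7,Culex,male,6
Abaam,7,non_target,unknown,6
Abaam,10,Culex,female,11
Abaam,10,Culex,male,4
Abaam,10,non_target,unknown,6
Abaam,11,Culex,female,62
Abaam,11,Culex,male,20
Abaam,11,non_target,unknown,6
Abaam,12,Culex,female,9
Abaam,12,Culex,male,3
Abaam,12,non_target,unknown,6
Abaam,13,Culex,female,7
Abaam,13,Culex,male,2
Abaam,13,non_target,unknown,6
Abaam,14,Culex,female,6
Abaam,14,Culex,male,2
Abaam,14,non_target,unknown,6
Abaam,15,Culex,female,3
Abaam,15,Culex,male,1
Abaam,15,non_target,unknown,6
Abaam,16,Culex,female,8
Abaam,16,Culex,male,2
Abaam,16,non_target,unknown,6
Pramkese,1,Aedes,female,2
Pramkese,1,Anopheles,female,2
Pramkese,1,Culex,female,60
Pramkese,1,Culex,male,19
Pramkese,1,Mansonia,female,1
Pramkese,1,non_target,unknown,6
Pramkese,2,Aedes,female,2
Pramkese,2,Anopheles,female,2
Pramkese,2,Culex,female,55
Pramkese,2,Culex,male,18
Pramkese,2,non_target,unknown,6
Pramkese,3,Aedes,female,2
Pramkese,3,Anopheles,female,2
Pramkese,3,Culex,female,16
Pramkese,3,Culex,male,5
Pramkese,3,non_target,unknown,6
Pramkese,4,Aedes,female,2
Pramkese,4,Anopheles,female,2
Pramkese,4,Culex,female,14
Pramkese,4,Culex,male,4
Pramkese,4,non_target,unknown,6
Pramkese,5,Aedes,female,2
Pramkese,5,Anopheles,female,2
Pramkese,5,Culex,female,12
Pramkese,5,Culex,male,4
Pramkese,5,non_target,unknown,6
Pramkese,6,Aedes,female,2
Pramkese,6,Anopheles,female,2
Pramkese,6,Culex,female,9
Pramkese,6,Culex,male,3
Pramkese,6,non_target,unknown,6
Pramkese,7,Aedes,female,1
Pramkese,7,Aedes,male,1
Pramkese,7,Anopheles,female,1
Pramkese,7,Anopheles,male,1
Pramkese,7,Culex,female,8
Pramkese,7,Culex,male,3
Pramkese,7,non_target,unknown,6
Pramkese,8,Aedes,female,1
Pramkese,8,Aedes,male,1
Pramkese,8,Anopheles,female,1
Pramkese,8,Anopheles,male,1
Pramkese,8,Culex,female,22
Pramkese,8,Culex,male,7
Pramkese,8,non_target,unknown,6
Pramkese,9,Aedes,female,1
Pramkese,9,Aedes,male,1
Pramkese,9,Anopheles,female,1
Pramkese,9,Anopheles,male,1
Pramkese,9,Culex,female,30
Pramkese,9,Culex,male,10
Pramkese,9,non_target,unknown,6
Pramkese,10,Aedes,female,1
Pramkese,10,Aedes,male,1
Pramkese,10,Anopheles,female,1
Pramkese,10,Anopheles,male,1
Pramkese,10,Culex,female,6
Pramkese,10,Culex,male,2
Pramkese,10,non_target,unknown,6
Pramkese,11,Aedes,female,1
Pramkese,11,Aedes,male,1
Pramkese,11,Anopheles,female,1
Pramkese,11,Anopheles,male,1
Pramkese,11,Culex,female,10
Pramkese,11,Culex,male,3
Pramkese,11,non_target,unknown,6
Pramkese,12,Aedes,female,1
Pramkese,12,Aedes,male,1
Pramkese,12,Anopheles,female,1
Pramkese,12,Anopheles,male,1
Pramkese,12,Culex,female,5
Pramkese,12,Culex,male,1
Pramkese,12,non_target,unknown,5
Pramkese,13,Aedes,female,1
Pramkese,13,Aedes,male,1
Pramkese,13,Anopheles,female,1
Pramkese,13,Anopheles,male,1
Pramkese,13,Culex,female,4
Pramkese,13,Culex,male,1
Pramkese,13,non_target,unknown,5
Pramkese,14,Aedes,female,1
Pramkese,14,Aedes,male,1
Pramkese,14,Anopheles,female,1
Pramkese,14,Anopheles,male,1
Pramkese,14,Culex,female,3
Pramkese,14,Culex,male,1
Pramkese,14,non_target,unknown,5
Pramkese,15,Aedes,female,1
Pramkese,15,Aedes,male,1
Pramkese,15,Anopheles,female,1
Pramkese,15,Anopheles,male,1
Pramkese,15,Culex,female,2
Pramkese,15,Culex,male,1
Pramkese,15,non_target,unknown,5
Pramkese,16,Aedes,female,1
Pramkese,16,Anopheles,female,1
Pramkese,16,Culex,female,22
Pramkese,16,Culex,male,7
Pramkese,16,non_target,unknown,5
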