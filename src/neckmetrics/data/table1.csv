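specimen_id,taxon,element_label,serial_index,region,facet,convention,vertical,horizontal,centrum_length,units
giraffe,Giraffa camelopardalis,C2,2,cervical,posterior,midline,437,638,,arbitrary
giraffe,Giraffa camelopardalis,C3,3,cervical,posterior,midline,499,647,,arbitrary
giraffe,Giraffa camelopardalis,C4,4,cervical,posterior,midline,471,600,,arbitrary
giraffe,Giraffa camelopardalis,C5,5,cervical,posterior,midline,513,665,,arbitrary
giraffe,Giraffa camelopardalis,C6,6,cervical,posterior,midline,531,731,,arbitrary
giraffe,Giraffa camelopardalis,C7,7,cervical,posterior,midline,510,581,,arbitrary
monitor,Varanus exanthematicus,C3,3,cervical,posterior,midline,155,255,,arbitrary
monitor,Varanus exanthematicus,C4,4,cervical,posterior,midline,181,308,,arbitrary
monitor,Varanus exanthematicus,C5,5,cervical,posterior,midline,179,301,,arbitrary
monitor,Varanus exanthematicus,C6,6,cervical,posterior,midline,194,287,,arbitrary
monitor,Varanus exanthematicus,C7,7,cervical,posterior,midline,189,308,,arbitrary
alligator,Alligator mississippiensis,C5,5,cervical,anterior,midline,202,217,,arbitrary
alligator,Alligator mississippiensis,C6,6,cervical,anterior,midline,203,233,,arbitrary
alligator,Alligator mississippiensis,C7,7,cervical,anterior,midline,213,240,,arbitrary
alligator,Alligator mississippiensis,C8,8,cervical,anterior,midline,203,265,,arbitrary
alligator,Alligator mississippiensis,D1,9,dorsal,anterior,midline,198,236,,arbitrary
alligator,Alligator mississippiensis,D2,10,dorsal,anterior,midline,203,244,,arbitrary
ostrich,Struthio camelus,C5,5,cervical,posterior,maximum,156,207,,arbitrary
ostrich,Struthio camelus,C6,6,cervical,posterior,maximum,173,219,,arbitrary
ostrich,Struthio camelus,C7,7,cervical,posterior,maximum,177,232,,arbitrary
ostrich,Struthio camelus,C8,8,cervical,posterior,maximum,161,237,,arbitrary
ostrich,Struthio camelus,C9,9,cervical,posterior,maximum,172,223,,arbitrary
ostrich,Struthio camelus,C10,10,cervical,posterior,maximum,170,235,,arbitrary
ostrich,Struthio camelus,C11,11,cervical,posterior,maximum,180,221,,arbitrary
CM 84,Diplodocus carnegii,C2,2,cervical,posterior,midline,33,36,,arbitrary
CM 84,Diplodocus carnegii,C3,3,cervical,posterior,midline,39,47,,arbitrary
CM 84,Diplodocus carnegii,C4,4,cervical,posterior,midline,52,55,,arbitrary
CM 84,Diplodocus carnegii,C5,5,cervical,posterior,midline,52,62,,arbitrary
CM 84,Diplodocus carnegii,C6,6,cervical,posterior,midline,61,69,,arbitrary
CM 84,Diplodocus carnegii,C7,7,cervical,posterior,midline,70,80,,arbitrary
CM 84,Diplodocus carnegii,C8,8,cervical,posterior,midline,68,75,,arbitrary
CM 84,Diplodocus carnegii,C9,9,cervical,posterior,midline,91,104,,arbitrary
CM 84,Diplodocus carnegii,C10,10,cervical,posterior,midline,102,109,,arbitrary
CM 84,Diplodocus carnegii,C11,11,cervical,posterior,midline,117,144,,arbitrary
CM 84,Diplodocus carnegii,C12,12,cervical,posterior,midline,139,160,,arbitrary
CM 84,Diplodocus carnegii,C13,13,cervical,posterior,midline,143,156,,arbitrary
CM 84,Diplodocus carnegii,C14,14,cervical,posterior,midline,134,199,,arbitrary
CM 84,Diplodocus carnegii,C15,15,cervical,posterior,midline,156,173,,arbitrary
MB.R.2180,Giraffatitan brancai,C2,2,cervical,posterior,midline,864,717,,arbitrary
MB.R.2180,Giraffatitan brancai,C3,3,cervical,posterior,midline,695,678,,arbitrary
MB.R.2180,Giraffatitan brancai,C4,4,cervical,posterior,midline,672,644,,arbitrary
MB.R.2180,Giraffatitan brancai,C5,5,cervical,posterior,midline,675,1014,,arbitrary
MB.R.2180,Giraffatitan brancai,C6,6,cervical,posterior,midline,828,1188,,arbitrary
MB.R.2180,Giraffatitan brancai,C7,7,cervical,posterior,midline,640,708,,arbitrary
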